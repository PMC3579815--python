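"""HGVS ``c.``/``r.`` parsing, aberrant-mRNA reconstruction and protein
consequences.

Supported grammar is the subset needed for splice-region work: SNVs,
deletions, insertions and delins with CDS-relative anchors and signed
intronic offsets on the DNA level; and on the RNA level bracketed event
lists ``r.[...]`` mixing normal transcripts (``=``), deletions (exon
skipping or partial exon loss), intron retentions written as insertions of
an intronic span, and substitutions.  No duplications, inversions or
protein-level parsing.

Consequence prediction is pure coordinate arithmetic where no sequence is
available -- frame status from the net coding-length change, codon numbers
from ``floor((c-1)/3)+1`` -- and full translation (premature-termination
codon location, ``p.`` strings with the fsX count) when the transcript
carries its sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from statsmodels.stats.proportion import proportion_confint

from .transcripts import TranscriptModel
from .variant_effects import Variant

# ---------------------------------------------------------------------------
# HGVS c. parsing
# ---------------------------------------------------------------------------

_POS = r"(\d+)([+-]\d+)?"
_C_RE = re.compile(
    rf"c\.{_POS}(?:_{_POS})?"
    r"(?:"
    r"(?P<ref_snv>[ACGT])>(?P<alt_snv>[ACGT])"
    r"|del(?P<del_seq>[ACGT]*)(?:ins(?P<delins_alt>[ACGT]+))?"
    r"|ins(?P<ins_seq>[ACGT]+)"
    r")$"
)


def normalize_hgvs(text: str) -> str:
    """Normalize unicode minus signs to ASCII hyphen and drop spaces."""
    return text.replace("−", "-").replace("–", "-").replace(" ", "").strip()


class HgvsParseError(ValueError):
    def __init__(self, text: str, offset: int, message: str = "unparseable") -> None:
        super().__init__(f"{message} at character {offset} in {text!r}")
        self.offset = offset


def parse_hgvs_c(text: str) -> Variant:
    """Parse a cDNA-level HGVS descriptor into a :class:`Variant`."""
    norm = normalize_hgvs(text)
    m = _C_RE.match(norm)
    if m is None:
        # best-effort offset: longest prefix that still matches the grammar
        for k in range(len(norm), -1, -1):
            if any(_C_RE.match(norm[:k] + tail) for tail in ("A>C", "delA", "")):
                break
        raise HgvsParseError(text, k)
    anchor, off, end_anchor, end_off = m.group(1, 2, 3, 4)
    a, o = int(anchor), int(off or 0)
    if end_anchor is None:
        ea, eo = a, o
    else:
        ea, eo = int(end_anchor), int(end_off or 0)
    if m.group("ref_snv"):
        kind, ref, alt = "SNV", m.group("ref_snv"), m.group("alt_snv")
    elif m.group("ins_seq"):
        kind, ref, alt = "ins", "", m.group("ins_seq")
    elif m.group("delins_alt"):
        kind, ref, alt = "delins", m.group("del_seq") or "", m.group("delins_alt")
    else:
        kind, ref, alt = "del", m.group("del_seq") or "", ""
    return Variant(
        hgvs_c=norm,
        anchor_cdna_pos=a,
        intron_offset=o,
        end_anchor=ea,
        end_offset=eo,
        kind=kind,
        ref_allele=ref,
        alt_allele=alt,
    )


# ---------------------------------------------------------------------------
# HGVS r. parsing
# ---------------------------------------------------------------------------

NORMAL = "normal"
DELETION = "deletion"
RETENTION = "intron_retention"
SUBSTITUTION = "substitution"

# refined via a transcript model
EXON_SKIP = "exon_skip"
PARTIAL_LOSS = "partial_loss"

_R_DEL = re.compile(r"(\d+)_(\d+)del$")
_R_SUB = re.compile(r"(\d+)([acgu])>([acgu])$")
_R_INS = re.compile(r"(\d+)_(\d+)ins(\d+)([+-]\d+)_(\d+)([+-]\d+)$")


@dataclass
class RnaEvent:
    """One element of an observed mRNA change."""

    kind: str
    start: int = 0  # deletion span / substitution position (cDNA, 1-based)
    end: int = 0
    ref: str = ""
    alt: str = ""
    after_pos: int = 0  # retention: last exonic base before the insertion
    retained_len: int = 0
    intron_anchors: tuple[int, int, int, int] | None = None  # a1, o1, a2, o2
    note: str = ""  # verbatim '; ...' suffix, stored unvalidated

    @property
    def net_length_change(self) -> int:
        if self.kind == DELETION:
            return -(self.end - self.start + 1)
        if self.kind == RETENTION:
            return self.retained_len
        return 0

    def format(self) -> str:
        if self.kind == NORMAL:
            body = "="
        elif self.kind == DELETION:
            body = f"{self.start}_{self.end}del"
        elif self.kind == SUBSTITUTION:
            body = f"{self.start}{self.ref}>{self.alt}"
        else:
            a1, o1, a2, o2 = self.intron_anchors
            body = f"{self.after_pos}_{self.after_pos + 1}ins{a1}{o1:+d}_{a2}{o2:+d}"
        return body + (f";{self.note}" if self.note else "")


@dataclass
class MrnaChange:
    """Parsed ``r.`` descriptor: the transcripts observed for one allele."""

    source: str
    events: list[RnaEvent] = field(default_factory=list)
    up_regulated_isoform: bool = False

    def aberrant_events(self) -> list[RnaEvent]:
        return [e for e in self.events if e.kind != NORMAL]

    def format(self) -> str:
        return "r.[" + ",".join(e.format() for e in self.events) + "]"


def _parse_r_event(element: str, source: str) -> RnaEvent:
    body, _, note = element.partition(";")
    note = note.strip()
    if body == "=":
        return RnaEvent(kind=NORMAL, note=note)
    if m := _R_DEL.match(body):
        s, e = int(m.group(1)), int(m.group(2))
        if e < s:
            raise HgvsParseError(source, source.find(body), "inverted deletion span")
        return RnaEvent(kind=DELETION, start=s, end=e, note=note)
    if m := _R_SUB.match(body):
        return RnaEvent(
            kind=SUBSTITUTION,
            start=int(m.group(1)),
            end=int(m.group(1)),
            ref=m.group(2),
            alt=m.group(3),
            note=note,
        )
    if m := _R_INS.match(body):
        after, nxt = int(m.group(1)), int(m.group(2))
        a1, o1, a2, o2 = (int(m.group(i)) for i in (3, 4, 5, 6))
        if nxt != after + 1:
            raise HgvsParseError(source, source.find(body), "insertion site not adjacent")
        length = o2 - o1 + 1
        if length <= 0:
            raise HgvsParseError(source, source.find(body), "empty retained span")
        return RnaEvent(
            kind=RETENTION,
            after_pos=after,
            retained_len=length,
            intron_anchors=(a1, o1, a2, o2),
            note=note,
        )
    raise HgvsParseError(source, source.find(body) if body else 0)


def parse_hgvs_r(text: str) -> MrnaChange:
    """Parse an RNA-level HGVS descriptor (``r.[...]`` event list)."""
    norm = normalize_hgvs(text)
    if not norm.startswith("r."):
        raise HgvsParseError(text, 0, "expected leading 'r.'")
    body = norm[2:]
    if body.startswith("[") and body.endswith("]"):
        body = body[1:-1]
    elif body.startswith("[") or body.endswith("]"):
        raise HgvsParseError(text, len(norm) - 1, "unbalanced brackets")
    if not body:
        raise HgvsParseError(text, 2, "empty descriptor")
    events = [_parse_r_event(el, norm) for el in body.split(",")]
    return MrnaChange(source=norm, events=events)


def classify_rna_event(event: RnaEvent, transcript: TranscriptModel) -> str:
    """Refine an event kind against the exon structure.

    A deletion whose span coincides with one or more complete consecutive
    exons is an exon skip; any other deletion is a partial exon loss.
    """
    if event.kind != DELETION:
        return event.kind
    bounds = transcript.exon_cdna_bounds()
    starts = {lo: i for i, (lo, _) in enumerate(bounds)}
    ends = {hi: i for i, (_, hi) in enumerate(bounds)}
    if event.start in starts and event.end in ends and ends[event.end] >= starts[event.start]:
        return EXON_SKIP
    return PARTIAL_LOSS


# ---------------------------------------------------------------------------
# aberrant mature mRNA
# ---------------------------------------------------------------------------


def mature_mrna(
    transcript: TranscriptModel, change: MrnaChange | RnaEvent
) -> tuple[str, dict[int, int]]:
    """Build the aberrant mature mRNA and a coordinate map.

    Returns the CDS-relative aberrant sequence and a map from each
    *surviving* original cDNA position (1-based) to its 1-based position in
    the aberrant sequence.  Requires the transcript sequence (retained
    introns are copied from it).  Overlapping events are rejected.
    """
    events = change.aberrant_events() if isinstance(change, MrnaChange) else [change]
    cds = transcript.cds_sequence()
    L = len(cds)
    spans: list[tuple[int, int, RnaEvent]] = []
    for ev in events:
        if ev.kind == DELETION or ev.kind == SUBSTITUTION:
            if not (1 <= ev.start <= ev.end <= L):
                raise ValueError(f"event span {ev.start}_{ev.end} outside transcript (1..{L})")
            spans.append((ev.start, ev.end, ev))
        elif ev.kind == RETENTION:
            if not (1 <= ev.after_pos < L):
                raise ValueError(f"retention anchor {ev.after_pos} outside transcript")
            spans.append((ev.after_pos + 1, ev.after_pos, ev))  # zero-width
    spans.sort(key=lambda t: (t[0], t[1]))
    for (s1, e1, _), (s2, _, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("overlapping events in one transcript")

    out: list[str] = []
    pos_map: dict[int, int] = {}
    cursor = 1  # next original position to copy

    def copy_through(upto: int) -> None:
        nonlocal cursor
        for p in range(cursor, upto + 1):
            out.append(cds[p - 1])
            pos_map[p] = len(out)
        cursor = upto + 1

    for s, e, ev in spans:
        if ev.kind == DELETION:
            copy_through(s - 1)
            cursor = e + 1
        elif ev.kind == SUBSTITUTION:
            copy_through(s - 1)
            out.append(ev.alt.upper().replace("U", "T"))
            pos_map[s] = len(out)
            cursor = s + 1
        else:  # retention
            copy_through(ev.after_pos)
            a1, o1, a2, o2 = ev.intron_anchors
            g1 = transcript.cdna_to_gene_local(a1, o1)
            g2 = transcript.cdna_to_gene_local(a2, o2)
            seq = transcript._require_sequence()
            out.extend(seq[g1 : g2 + 1])
    copy_through(L)
    return "".join(out), pos_map


# ---------------------------------------------------------------------------
# protein consequence
# ---------------------------------------------------------------------------

FRAMESHIFT_PTC = "frameshift_PTC"
INFRAME_DEL = "inframe_del"
INFRAME_INS = "inframe_ins"
MISSENSE = "missense"
SILENT = "silent"
NONSENSE = "nonsense"
CODING_SUBSTITUTION = "substitution"  # aa effect undetermined without sequence
START_STOP_AFFECTED = "start_stop_affected"
NONE = "none"


@dataclass
class ProteinConsequence:
    kind: str
    first_affected_codon: int | None = None
    ptc_codon: int | None = None
    residues_deleted: int | None = None
    hgvs_p: str | None = None


def codon_number(cdna_pos: int) -> int:
    """1-based codon index of a CDS-relative position: floor((c-1)/3)+1."""
    if cdna_pos < 1:
        raise ValueError("cDNA position must be >= 1")
    return (cdna_pos - 1) // 3 + 1


def _translate(seq: str) -> str:
    # trim to a whole number of codons; Biopython would warn otherwise
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate())


def _first_stop(protein: str) -> int | None:
    k = protein.find("*")
    return k + 1 if k >= 0 else None


def predict_event_consequence(
    transcript: TranscriptModel, event: RnaEvent
) -> ProteinConsequence:
    """Predict the protein-level outcome of a single mRNA event.

    Without a transcript sequence the prediction is purely arithmetic:
    frame status, first affected codon, residues deleted.  With a sequence
    the aberrant mRNA is translated to locate the premature termination
    codon and emit a ``p.`` string.
    """
    if event.kind == NORMAL:
        return ProteinConsequence(kind=NONE, hgvs_p="p.=")
    cds_len = transcript.cds_len
    have_seq = transcript.sequence is not None

    if event.kind == SUBSTITUTION:
        p = event.start
        if p <= 3 or p > cds_len - 3:
            return ProteinConsequence(kind=START_STOP_AFFECTED, first_affected_codon=codon_number(p))
        codon = codon_number(p)
        if not have_seq:
            return ProteinConsequence(kind=CODING_SUBSTITUTION, first_affected_codon=codon)
        aberrant, _ = mature_mrna(transcript, event)
        wt_aa = _translate(transcript.cds_sequence())[codon - 1]
        mut_aa = _translate(aberrant)[codon - 1]
        if mut_aa == wt_aa:
            return ProteinConsequence(kind=SILENT, first_affected_codon=codon, hgvs_p="p.=")
        if mut_aa == "*":
            return ProteinConsequence(
                kind=NONSENSE, first_affected_codon=codon, ptc_codon=codon,
                hgvs_p=f"p.{seq3(wt_aa)}{codon}X",
            )
        return ProteinConsequence(
            kind=MISSENSE, first_affected_codon=codon,
            hgvs_p=f"p.{seq3(wt_aa)}{codon}{seq3(mut_aa)}",
        )

    if event.kind == DELETION:
        s, e = event.start, event.end
        first = codon_number(s)
        if s <= 3 or e > cds_len - 3:
            return ProteinConsequence(kind=START_STOP_AFFECTED, first_affected_codon=first)
        n = e - s + 1
        in_frame = n % 3 == 0
    else:  # intron retention
        s = event.after_pos + 1  # first altered position
        first = codon_number(s)
        if s <= 3 or event.after_pos >= cds_len - 2:
            return ProteinConsequence(kind=START_STOP_AFFECTED, first_affected_codon=first)
        n = event.retained_len
        in_frame = n % 3 == 0

    if not have_seq:
        if in_frame and event.kind == DELETION:
            return ProteinConsequence(
                kind=INFRAME_DEL, first_affected_codon=first, residues_deleted=n // 3
            )
        if in_frame:
            return ProteinConsequence(kind=INFRAME_INS, first_affected_codon=first)
        return ProteinConsequence(
            kind=FRAMESHIFT_PTC, first_affected_codon=first, ptc_codon=None,
            hgvs_p=f"p.({first})fs",
        )

    wt_protein = _translate(transcript.cds_sequence())
    aberrant, _ = mature_mrna(transcript, event)
    protein = _translate(aberrant)
    natural_stop = cds_len // 3
    stop = _first_stop(protein)
    wt_aa = wt_protein[first - 1]

    if in_frame:
        if stop is not None and stop != len(protein) and stop < natural_stop:
            # junctional (or retained-sequence) stop despite preserved frame
            return ProteinConsequence(
                kind=NONSENSE, first_affected_codon=first, ptc_codon=stop,
                hgvs_p=f"p.{seq3(wt_aa)}{first}X" if stop == first else None,
            )
        if event.kind == DELETION:
            n_res = n // 3
            last = first + n_res - 1
            last_aa = wt_protein[last - 1]
            return ProteinConsequence(
                kind=INFRAME_DEL, first_affected_codon=first, residues_deleted=n_res,
                hgvs_p=f"p.{seq3(wt_aa)}{first}_{seq3(last_aa)}{last}del",
            )
        return ProteinConsequence(kind=INFRAME_INS, first_affected_codon=first)

    # name the first residue that actually differs (the frameshift junction
    # codon can happen to encode the wild-type amino acid)
    diff = first
    while diff <= min(len(protein), len(wt_protein)) and protein[diff - 1] == wt_protein[diff - 1]:
        diff += 1
    if diff > len(protein):
        return ProteinConsequence(
            kind=FRAMESHIFT_PTC, first_affected_codon=first, ptc_codon=None,
            hgvs_p=f"p.({first})fs",
        )
    wt_diff_aa = wt_protein[diff - 1] if diff <= len(wt_protein) else "?"
    mut_diff_aa = protein[diff - 1]
    if mut_diff_aa == "*":
        return ProteinConsequence(
            kind=FRAMESHIFT_PTC, first_affected_codon=first, ptc_codon=diff,
            hgvs_p=f"p.{seq3(wt_diff_aa)}{diff}X",
        )
    if stop is None:
        return ProteinConsequence(
            kind=FRAMESHIFT_PTC, first_affected_codon=first, ptc_codon=None,
            hgvs_p=f"p.{seq3(wt_diff_aa)}{diff}{seq3(mut_diff_aa)}fs",
        )
    fs_count = stop - diff + 1
    return ProteinConsequence(
        kind=FRAMESHIFT_PTC, first_affected_codon=first, ptc_codon=stop,
        hgvs_p=f"p.{seq3(wt_diff_aa)}{diff}{seq3(mut_diff_aa)}fsX{fs_count}",
    )


def predict_consequence(
    transcript: TranscriptModel, change: MrnaChange
) -> list[ProteinConsequence]:
    """One protein consequence per aberrant event of an mRNA change."""
    return [predict_event_consequence(transcript, ev) for ev in change.aberrant_events()]


# ---------------------------------------------------------------------------
# allelic proportions and clinical classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllelicProportion:
    k: int
    n: int
    percent: int
    ci_low: float
    ci_high: float


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def allelic_proportion(variant_allele_clones: int, total_clones: int) -> AllelicProportion:
    """Clone-count proportion, rounded half away from zero, with exact
    (Clopper-Pearson) 95% confidence interval."""
    k, n = variant_allele_clones, total_clones
    if n <= 0:
        raise ValueError("total clone count must be positive")
    if not 0 <= k <= n:
        raise ValueError("variant clone count must lie in [0, total]")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return AllelicProportion(
        k=k, n=n, percent=round_half_away(100.0 * k / n), ci_low=float(lo), ci_high=float(hi)
    )


MONO = "mono"
BI = "bi"
NOT_ASSESSABLE = "not_assessable"

CLASS_PATHOGENIC = "5"
CLASS_LIKELY_PATHOGENIC = "4"
CLASS_4_OR_5 = "4 or 5"
CLASS_LIKELY_NEUTRAL = "2"
UNCLASSIFIED = "unclassified"


def classify_clinical(
    spliceogenic: bool,
    allelic_expression: str = NOT_ASSESSABLE,
    benign_missense_prior: bool | None = None,
    intronic: bool = False,
) -> str:
    """Five-tier clinical class from splicing outcome and allelic expression.

    Spliceogenic variants: class 5 when only the mutant allele silences
    normal transcript (mono-allelic normal expression), class 4 when normal
    transcript persists from both alleles, "4 or 5" when not assessable.
    Non-spliceogenic variants: class 2 (likely neutral) for intronic
    changes or missense changes with a benign prior (an external input,
    e.g. an alignment-based missense classifier); otherwise explicitly
    unclassified.
    """
    if spliceogenic:
        if allelic_expression == MONO:
            return CLASS_PATHOGENIC
        if allelic_expression == BI:
            return CLASS_LIKELY_PATHOGENIC
        if allelic_expression == NOT_ASSESSABLE:
            return CLASS_4_OR_5
        raise ValueError(f"unknown allelic expression {allelic_expression!r}")
    if intronic or benign_missense_prior:
        return CLASS_LIKELY_NEUTRAL
    return UNCLASSIFIED
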