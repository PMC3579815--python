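"""Variant application, delta-score formulas and alternative-site scanning.

The two percent-difference formulas mirror how splice-predictor outputs are
compared between wild-type and mutated sequences:

* PWM-style scores (SSPS): ``100 * (SSPS_mut - SSPS_wt) / SSPS_wt`` --
  defined only when the wild-type site is recognized (SSPS_wt > 0); a
  complete loss of the site gives exactly -100.
* information scores: ``100 * (2**(Ri_mut - Ri_wt) - 1)`` -- a 1-bit drop
  is -50%, a 1-bit gain +100%, reflecting the 2-fold-per-bit binding
  affinity scale.  Bounded below by -100 (open), unbounded above.

``find_alternative_sites`` scans +/- 500 bp around a damaged natural site
in the mutated sequence and tags every same-type candidate as *cryptic*
(already scoring above the floor in the wild-type sequence) or *novel*
(created by the variant).
"""

from __future__ import annotations

from dataclasses import dataclass

from .splice_models import (
    DEFAULT_CV_FLOOR,
    DEFAULT_RI_FLOOR,
    ScoredSite,
    SpliceModel,
    scan_sites,
)
from .transcripts import TranscriptModel

GROUP_A = "A"
GROUP_B = "B"
GROUP_OTHER = "other"

#: splice-region footprint (intron offsets / exonic distances) for group B
B_DONOR_INTRON = range(3, 9)  # +3..+8
B_ACCEPTOR_INTRON = range(3, 13)  # -3..-12
B_EXONIC_DONOR = 3  # last 3 exonic bases
B_EXONIC_ACCEPTOR = 2  # first 2 exonic bases


@dataclass
class Variant:
    """A parsed cDNA-level (HGVS ``c.``) sequence variant.

    Coordinates are 1-based CDS-relative anchors with signed intronic
    offsets; ``end_anchor``/``end_offset`` equal the start for single-base
    variants.
    """

    hgvs_c: str
    anchor_cdna_pos: int
    intron_offset: int
    end_anchor: int
    end_offset: int
    kind: str  # SNV | del | ins | delins
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "SNV" and (len(self.ref_allele) != 1 or len(self.alt_allele) != 1):
            raise ValueError(f"{self.hgvs_c}: SNV must have single-base ref and alt")
        if self.kind == "del" and self.alt_allele:
            raise ValueError(f"{self.hgvs_c}: deletion must have empty alt allele")

    def format(self) -> str:
        """Canonical HGVS c. string (ASCII hyphen-minus for minus)."""

        def pos(anchor: int, offset: int) -> str:
            if offset == 0:
                return str(anchor)
            return f"{anchor}{offset:+d}"

        left = pos(self.anchor_cdna_pos, self.intron_offset)
        span = (
            left
            if (self.anchor_cdna_pos, self.intron_offset)
            == (self.end_anchor, self.end_offset)
            else f"{left}_{pos(self.end_anchor, self.end_offset)}"
        )
        if self.kind == "SNV":
            return f"c.{span}{self.ref_allele}>{self.alt_allele}"
        if self.kind == "del":
            return f"c.{span}del{self.ref_allele}"
        if self.kind == "ins":
            return f"c.{span}ins{self.alt_allele}"
        return f"c.{span}del{self.ref_allele}ins{self.alt_allele}"

    # -- gene-local projection --------------------------------------------

    def gene_local_span(self, transcript: TranscriptModel) -> tuple[int, int]:
        """Affected gene-local span, 0-based half-open.

        For insertions the span is empty, located between the two anchor
        bases.
        """
        g_start = transcript.cdna_to_gene_local(self.anchor_cdna_pos, self.intron_offset)
        g_end = transcript.cdna_to_gene_local(self.end_anchor, self.end_offset)
        if self.kind == "ins":
            return g_start + 1, g_start + 1
        if g_end < g_start:
            raise ValueError(f"{self.hgvs_c}: inverted span in gene-local projection")
        return g_start, g_end + 1

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


def apply_variant(
    sequence: str,
    span_start: int,
    span_end: int,
    ref_allele: str,
    alt_allele: str,
) -> str:
    """Replace ``sequence[span_start:span_end]`` by ``alt_allele``.

    When a reference allele is stated it must match the sequence.
    """
    if span_start < 0 or span_end > len(sequence) or span_start > span_end:
        raise ValueError(
            f"variant span [{span_start}, {span_end}) out of bounds for "
            f"sequence of length {len(sequence)}"
        )
    observed = sequence[span_start:span_end]
    if ref_allele and observed.upper() != ref_allele.upper():
        raise ValueError(
            f"reference mismatch at [{span_start}, {span_end}): expected "
            f"{ref_allele!r}, observed {observed!r}"
        )
    return sequence[:span_start] + alt_allele + sequence[span_end:]


def percent_diff_ssps(ssps_wt: float, ssps_mut: float) -> float:
    """Relative percent difference of PWM-style scores: 100*(mut-wt)/wt."""
    if ssps_wt <= 0:
        raise ValueError(
            "site not recognized in wild type (SSPS_wt <= 0): analysis non-informative"
        )
    return 100.0 * (ssps_mut - ssps_wt) / ssps_wt


def percent_diff_ri(ri_wt: float, ri_mut: float) -> float:
    """Percent change in binding affinity: 100*(2**(Ri_mut-Ri_wt) - 1)."""
    for name, v in (("ri_wt", ri_wt), ("ri_mut", ri_mut)):
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError(f"{name} must be finite")
    return 100.0 * (2.0 ** (ri_mut - ri_wt) - 1.0)


def map_position_through_edit(
    pos: int, span_start: int, span_end: int, alt_len: int
) -> int:
    """Project a wild-type coordinate into the mutated sequence.

    Positions inside the replaced span are clamped into the replacement
    (this is how a junction whose dinucleotide was deleted is re-located).
    """
    if pos <= span_start:
        return pos
    if pos >= span_end:
        return pos + alt_len - (span_end - span_start)
    return span_start + min(alt_len, pos - span_start)


def default_floor(scorer: str) -> float:
    return DEFAULT_CV_FLOOR if scorer == "cv" else DEFAULT_RI_FLOOR


@dataclass
class DeltaResult:
    """Outcome of scoring one natural site in wild-type vs mutated sequence."""

    predictor_id: str
    scorer: str
    wt_score: float | None
    mut_score: float | None
    percent_diff: float | None
    informative: bool
    call: str | None = None  # filled by evaluation.classify


def delta_for_site(
    model: SpliceModel,
    sequence: str,
    span_start: int,
    span_end: int,
    ref_allele: str,
    alt_allele: str,
    natural_site: int,
    scorer: str = "cv",
    floor: float | None = None,
    predictor_id: str = "in-house",
) -> DeltaResult:
    """Score a natural junction before/after a variant and take the delta.

    The analysis is *informative* only when the wild-type window scores at
    or above the detection floor.  After the edit the junction coordinate is
    re-located through the length change.  A mutated site whose percent
    score drops to zero (or whose window no longer fits) yields -100 on the
    SSPS scale.
    """
    if floor is None:
        floor = default_floor(scorer)
    wt = model.score_junction(sequence, natural_site, scorer)
    if wt is None:
        raise ValueError("natural site window does not fit inside the sequence")
    if wt < floor or (scorer == "cv" and wt <= 0):
        return DeltaResult(predictor_id, scorer, wt, None, None, informative=False)
    mutated = apply_variant(sequence, span_start, span_end, ref_allele, alt_allele)
    new_junction = map_position_through_edit(
        natural_site, span_start, span_end, len(alt_allele)
    )
    mut = model.score_junction(mutated, new_junction, scorer)
    if scorer == "cv":
        pct = -100.0 if mut is None else percent_diff_ssps(wt, mut)
    else:
        if mut is None:
            raise ValueError("mutated window out of bounds; Ri delta undefined")
        pct = percent_diff_ri(wt, mut)
    return DeltaResult(predictor_id, scorer, wt, mut, pct, informative=True)


@dataclass(frozen=True)
class AlternativeSite:
    """A cryptic or novel candidate site near a damaged natural junction."""

    site: ScoredSite
    tag: str  # cryptic | novel
    distance: int  # junction-to-junction, mutated coordinates

    @property
    def position(self) -> int:
        return self.site.position


def find_alternative_sites(
    model: SpliceModel,
    wt_sequence: str,
    mut_sequence: str,
    natural_site: int,
    span_start: int = 0,
    span_end: int = 0,
    alt_len: int = 0,
    half_window: int = 500,
    floor: float | None = None,
    scorer: str = "cv",
) -> list[AlternativeSite]:
    """Scan the mutated sequence around the natural site for candidates.

    ``natural_site`` is the wild-type junction coordinate; the edit span
    (``span_start``/``span_end``/``alt_len``, defaults meaning "no edit")
    maps it, and every candidate, between coordinate systems.  Candidates
    at the natural junction itself are excluded; each site is tagged
    *cryptic* when the corresponding wild-type junction already scores at
    or above the floor, *novel* otherwise, and reports its
    junction-to-junction distance in mutated coordinates.
    """
    if floor is None:
        floor = default_floor(scorer)
    shift_len = alt_len - (span_end - span_start)
    nat_mut = map_position_through_edit(natural_site, span_start, span_end, alt_len)
    lo = max(0, nat_mut - half_window)
    hi = min(len(mut_sequence), nat_mut + half_window + 1)
    candidates = scan_sites(model, mut_sequence, floor, scorer=scorer, region=(lo, hi))
    out: list[AlternativeSite] = []
    for site in candidates:
        if site.position == nat_mut:
            continue
        # inverse map: mutated coordinate -> wild-type coordinate
        if site.position <= span_start:
            wt_pos: int | None = site.position
        elif site.position >= span_start + alt_len:
            wt_pos = site.position - shift_len
        else:
            wt_pos = None  # junction lies inside inserted material
        tag = "novel"
        if wt_pos is not None:
            wt_score = model.score_junction(wt_sequence, wt_pos, scorer)
            if wt_score is not None and wt_score >= floor:
                tag = "cryptic"
        out.append(AlternativeSite(site=site, tag=tag, distance=site.position - nat_mut))
    return out


def _classify_base(anchor: int, offset: int, transcript: TranscriptModel) -> str:
    """Group membership of a single affected base."""
    if offset != 0:
        mag = abs(offset)
        if mag <= 2:
            return GROUP_A
        if offset > 0 and offset in B_DONOR_INTRON:
            return GROUP_B
        if offset < 0 and mag in B_ACCEPTOR_INTRON:
            return GROUP_B
        return GROUP_OTHER
    i = transcript.exon_containing(anchor)
    lo, hi = transcript.exon_cdna_bounds()[i]
    last_exon = i == transcript.n_exons - 1
    first_exon = i == 0
    if not last_exon and hi - anchor < B_EXONIC_DONOR:
        return GROUP_B
    if not first_exon and anchor - lo < B_EXONIC_ACCEPTOR:
        return GROUP_B
    return GROUP_OTHER


def assign_group(variant: Variant, transcript: TranscriptModel) -> str:
    """Classify a variant as group A (invariant GT/AG), B (splice region) or other.

    Every base affected by the variant is examined; A takes precedence over
    B, B over other.  For insertions the two flanking bases are examined.
    """
    if variant.kind == "ins":
        positions = [
            (variant.anchor_cdna_pos, variant.intron_offset),
            (variant.end_anchor, variant.end_offset),
        ]
        labels = [_classify_base(a, o, transcript) for a, o in positions]
    else:
        g_start, g_end = variant.gene_local_span(transcript)
        labels = [
            _classify_base(*transcript.gene_local_to_cdna(g), transcript)
            for g in range(g_start, g_end)
        ]
    if GROUP_A in labels:
        return GROUP_A
    if GROUP_B in labels:
        return GROUP_B
    return GROUP_OTHER
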