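"""Seeded synthetic multi-exon genes, splice-region variants and prediction
matrices.

The generator emulates the structure of a small clinical splice-variant
series: a multi-exon gene with consensus-conforming GT/AG sites, a variant
table split into group A (invariant dinucleotides, spliceogenic by
definition), group B (adjacent splice region, ground truth set by whether
the variant drops the natural-site information score below the detection
floor under the generating model) and deep controls, plus a variants x
predictors percent-difference matrix with planted informativeness and
false-positive structure.  Everything is driven by one pseudo-random
stream per bundle, so a seed reproduces the bundle byte-identically.

It does not emulate exonic splicing enhancers/silencers, branch points, or
tissue-specific factors; see the methods documentation for what passing
tests on this material does and does not show about real genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .splice_models import (
    ACCEPTOR_WINDOW,
    BASES,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_RI_FLOOR,
    DONOR_WINDOW,
    SiteWindow,
    SpliceModel,
)
from .transcripts import TranscriptModel
from .variant_effects import apply_variant, map_position_through_edit

# Positional base frequencies used as the generating truth for splice sites,
# modelled on the classical human donor/acceptor consensus compilations
# (approximate, rounded): donor spans -3..+6, acceptor -12..+2.
_DONOR_FREQS = [
    # A     C     G     T
    [0.33, 0.37, 0.18, 0.12],  # -3
    [0.60, 0.13, 0.14, 0.13],  # -2
    [0.08, 0.04, 0.81, 0.07],  # -1
    [0.00, 0.00, 1.00, 0.00],  # +1 (G)
    [0.00, 0.00, 0.00, 1.00],  # +2 (T)
    [0.50, 0.03, 0.45, 0.02],  # +3
    [0.72, 0.08, 0.12, 0.08],  # +4
    [0.06, 0.06, 0.84, 0.04],  # +5
    [0.15, 0.17, 0.22, 0.46],  # +6
]
_PYRIMIDINE = [0.10, 0.31, 0.11, 0.48]
_ACCEPTOR_FREQS = [
    _PYRIMIDINE,  # -12
    _PYRIMIDINE,  # -11
    _PYRIMIDINE,  # -10
    _PYRIMIDINE,  # -9
    _PYRIMIDINE,  # -8
    _PYRIMIDINE,  # -7
    _PYRIMIDINE,  # -6
    _PYRIMIDINE,  # -5
    [0.24, 0.30, 0.21, 0.25],  # -4
    [0.04, 0.65, 0.01, 0.30],  # -3
    [1.00, 0.00, 0.00, 0.00],  # -2 (A)
    [0.00, 0.00, 1.00, 0.00],  # -1 (G)
    [0.25, 0.15, 0.50, 0.10],  # +1
    [0.25, 0.25, 0.25, 0.25],  # +2
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = ["GCT", "GAA", "CTG", "TCC"]


def _smooth(freqs: list[list[float]], pseudocount: float, n: int) -> np.ndarray:
    arr = np.array(freqs, dtype=float)
    counts = arr * n
    return (counts + pseudocount) / (n + 4.0 * pseudocount)


def consensus_donor_model(
    window: SiteWindow = DONOR_WINDOW, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> SpliceModel:
    """Donor model built from the bundled consensus frequencies (n=200)."""
    return SpliceModel(window, _smooth(_DONOR_FREQS, pseudocount, 200),
                       pseudocount=pseudocount, n_training=200)


def consensus_acceptor_model(
    window: SiteWindow = ACCEPTOR_WINDOW, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> SpliceModel:
    """Acceptor model built from the bundled consensus frequencies (n=200)."""
    return SpliceModel(window, _smooth(_ACCEPTOR_FREQS, pseudocount, 200),
                       pseudocount=pseudocount, n_training=200)


def sample_training_windows(
    model: SpliceModel, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw aligned training windows from a model (for retraining tests)."""
    return [model.sample_window(rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# gene generation
# ---------------------------------------------------------------------------


def generate_gene(
    seed: int | np.random.Generator,
    n_exons: int = 5,
    exon_len_range: tuple[int, int] = (80, 200),
    intron_len_range: tuple[int, int] = (300, 1200),
    donor_model: SpliceModel | None = None,
    acceptor_model: SpliceModel | None = None,
    gene_id: str = "SYNTH1",
) -> tuple[str, TranscriptModel]:
    """Generate a random multi-exon gene with consensus splice sites.

    Every intron starts GT and ends AG; each boundary window is sampled
    from the supplied (or default consensus) models; the mature mRNA
    starts with a planted ATG, ends with a stop codon, and contains no
    internal in-frame stop.  The CDS is the whole mature mRNA.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    donor_model = donor_model or consensus_donor_model()
    acceptor_model = acceptor_model or consensus_acceptor_model()
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    min_intron = 2 + donor_model.window.intronic + acceptor_model.window.intronic
    if intron_len_range[0] <= min_intron:
        raise ValueError(
            f"introns must exceed {min_intron} nt to hold both boundary windows"
        )
    min_exon = donor_model.window.exonic + acceptor_model.window.exonic + 3
    if exon_len_range[0] < min_exon:
        raise ValueError(f"exons must be at least {min_exon} nt")

    exon_lens = [int(rng.integers(*exon_len_range, endpoint=True)) for _ in range(n_exons)]
    # keep the mature length a codon multiple so the terminal stop is in frame
    total = sum(exon_lens)
    exon_lens[-1] += (-total) % 3
    intron_lens = [
        int(rng.integers(*intron_len_range, endpoint=True)) for _ in range(n_exons - 1)
    ]

    chars: list[str] = []
    exons: list[tuple[int, int]] = []
    g = 0
    for i, L in enumerate(exon_lens):
        chars.extend(BASES[j] for j in rng.integers(0, 4, size=L))
        exons.append((g, g + L))
        g += L
        if i < n_exons - 1:
            chars.extend(BASES[j] for j in rng.integers(0, 4, size=intron_lens[i]))
            g += intron_lens[i]
    # boundary windows
    for i in range(n_exons - 1):
        donor_j = exons[i][1]
        w = donor_model.sample_window(rng)
        start = donor_model.window.window_start(donor_j)
        chars[start : start + len(w)] = list(w)
        acceptor_j = exons[i + 1][0]
        w = acceptor_model.sample_window(rng)
        start = acceptor_model.window.window_start(acceptor_j)
        chars[start : start + len(w)] = list(w)

    transcript = TranscriptModel(gene_id=gene_id, exons=exons, sequence="".join(chars))
    seq = list(transcript.sequence)

    def set_cdna(pos: int, base: str) -> None:
        seq[transcript.cdna_to_gene_local(pos)] = base

    for k, b in enumerate("ATG"):
        set_cdna(k + 1, b)
    L = transcript.mrna_len
    for k, b in enumerate("TAA"):
        set_cdna(L - 2 + k, b)
    transcript.sequence = "".join(seq)
    # recode internal in-frame stops (codon-aligned, cannot create new ones)
    mrna = transcript.mature_mrna()
    for c in range(1, L // 3 - 1):  # codons 2 .. last-1 (ATG and stop untouched)
        codon = mrna[3 * c : 3 * c + 3]
        if codon in _STOP_CODONS:
            repl = _SAFE_CODONS[int(rng.integers(0, len(_SAFE_CODONS)))]
            for k, b in enumerate(repl):
                set_cdna(3 * c + 1 + k, b)
    transcript.sequence = "".join(seq)
    return transcript.sequence, transcript


# ---------------------------------------------------------------------------
# variant generation
# ---------------------------------------------------------------------------


def _hgvs_snv(transcript: TranscriptModel, g: int, ref: str, alt: str) -> str:
    anchor, offset = transcript.gene_local_to_cdna(g)
    pos = str(anchor) if offset == 0 else f"{anchor}{offset:+d}"
    return f"c.{pos}{ref}>{alt}"


def _other_base(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def generate_variants(
    seed: int | np.random.Generator,
    transcript: TranscriptModel,
    n_group_a: int = 11,
    n_group_b: int = 13,
    n_controls: int = 5,
    donor_model: SpliceModel | None = None,
    acceptor_model: SpliceModel | None = None,
    ri_floor: float = DEFAULT_RI_FLOOR,
) -> pd.DataFrame:
    """Generate SNVs in splice regions with ground-truth spliceogenicity.

    Group A variants hit intron positions +/-1 or +/-2 and are spliceogenic
    by definition.  Group B variants hit the remaining splice-region
    footprint; their truth label is whether the natural-site information
    score in the mutated sequence drops to or below ``ri_floor`` under the
    generating model.  Controls sit deep in exons or introns and are
    non-spliceogenic.  Spliceogenic variants get a random allelic-expression
    status (mono / bi / not assessable); others are bi-allelic.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    donor_model = donor_model or consensus_donor_model()
    acceptor_model = acceptor_model or consensus_acceptor_model()
    seq = transcript._require_sequence()
    donors = transcript.donor_junctions()
    acceptors = transcript.acceptor_junctions()

    # enumerate the candidate footprint: (junction, site_type, gene-local pos)
    a_sites: list[tuple[int, str, int]] = []
    b_sites: list[tuple[int, str, int]] = []
    for j in donors:
        a_sites += [(j, "donor", j), (j, "donor", j + 1)]  # +1, +2
        b_sites += [(j, "donor", j + k) for k in range(2, 8)]  # +3..+8
        b_sites += [(j, "donor", j - k) for k in (1, 2, 3)]  # last 3 exonic
    for j in acceptors:
        a_sites += [(j, "acceptor", j - 1), (j, "acceptor", j - 2)]  # -1, -2
        b_sites += [(j, "acceptor", j - k) for k in range(3, 13)]  # -3..-12
        b_sites += [(j, "acceptor", j), (j, "acceptor", j + 1)]  # first 2 exonic
    if n_group_a > len(a_sites) or n_group_b > len(b_sites):
        raise ValueError("splice-region footprint exhausted for requested counts")

    deep: list[int] = []
    boundaries = set(donors) | set(acceptors)
    for g in range(len(seq)):
        if min(abs(g - b) for b in boundaries) > 40:
            deep.append(g)

    rows = []
    picks_a = rng.choice(len(a_sites), size=n_group_a, replace=False)
    for k in picks_a:
        j, stype, g = a_sites[int(k)]
        ref = seq[g]
        alt = _other_base(ref, rng)
        rows.append(("A", j, stype, g, ref, alt, True))
    picks_b = rng.choice(len(b_sites), size=n_group_b, replace=False)
    for k in picks_b:
        j, stype, g = b_sites[int(k)]
        ref = seq[g]
        alt = _other_base(ref, rng)
        model = donor_model if stype == "donor" else acceptor_model
        mutated = apply_variant(seq, g, g + 1, ref, alt)
        ri_mut = model.score_junction(mutated, j, scorer="ri")
        rows.append(("B", j, stype, g, ref, alt, bool(ri_mut is None or ri_mut <= ri_floor)))
    picks_c = rng.choice(len(deep), size=n_controls, replace=False)
    for k in picks_c:
        g = deep[int(k)]
        ref = seq[g]
        alt = _other_base(ref, rng)
        rows.append(("other", -1, "none", g, ref, alt, False))

    records = []
    for i, (group, j, stype, g, ref, alt, truth) in enumerate(rows):
        if truth:
            expr = ["mono", "bi", "not_assessable"][
                int(rng.choice(3, p=[0.6, 0.2, 0.2]))
            ]
        else:
            expr = "bi"
        records.append(
            {
                "id": f"v{i + 1:03d}",
                "hgvs_c": _hgvs_snv(transcript, g, ref, alt),
                "gene": transcript.gene_id,
                "group": group,
                "site_type": stype,
                "junction": j,
                "gene_local_pos": g,
                "ref": ref,
                "alt": alt,
                "truth_spliceogenic": truth,
                "allelic_expression": expr,
            }
        )
    return pd.DataFrame.from_records(records).set_index("id")


# ---------------------------------------------------------------------------
# prediction-matrix generation
# ---------------------------------------------------------------------------


def generate_matrix(
    seed: int | np.random.Generator,
    variant_table: pd.DataFrame,
    n_predictors: int = 9,
    informativeness_probs: float | list[float] = 1.0,
    fp_prob: float = 0.2,
    separation_floor: float = 30.0,
):
    """Generate a percent-difference matrix with planted error structure.

    Spliceogenic cells are decreases drawn uniformly from
    ``[-100, -separation_floor]``; per predictor, the first spliceogenic
    cell is pinned at exactly ``-separation_floor`` so the calibrated
    threshold equals the floor.  Non-spliceogenic cells cross the floor
    (i.e. become false positives) with probability ``fp_prob`` and
    otherwise stay strictly inside ``(-separation_floor, +30)``.  Cells are
    masked missing per predictor with one minus the informativeness
    probability.
    """
    from .evaluation import PredictionMatrix

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(informativeness_probs):
        informativeness_probs = [float(informativeness_probs)] * n_predictors
    if len(informativeness_probs) != n_predictors:
        raise ValueError("one informativeness probability per predictor required")
    if not 0.0 <= fp_prob <= 1.0:
        raise ValueError("fp_prob must be in [0, 1]")
    predictors = [f"pred{i + 1}" for i in range(n_predictors)]
    truth = variant_table["truth_spliceogenic"].astype(bool)
    values = pd.DataFrame(index=variant_table.index, columns=predictors, dtype=float)
    for p, inf_prob in zip(predictors, informativeness_probs):
        pinned = False
        for v in variant_table.index:
            if rng.random() > inf_prob:
                values.loc[v, p] = np.nan
                continue
            if truth[v]:
                if not pinned:
                    values.loc[v, p] = -separation_floor
                    pinned = True
                else:
                    values.loc[v, p] = -rng.uniform(separation_floor, 100.0)
            elif rng.random() < fp_prob:
                values.loc[v, p] = -rng.uniform(separation_floor, 100.0)
            else:
                values.loc[v, p] = rng.uniform(-0.9 * separation_floor, 30.0)
    return PredictionMatrix(values=values, truth=truth)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """A complete, regenerable synthetic study: gene + variants + matrix."""

    seed: int
    sequence: str
    transcript: TranscriptModel
    variants: pd.DataFrame
    matrix: "object"  # PredictionMatrix; avoids a module cycle in type pos
    params: dict = field(default_factory=dict)


def generate_bundle(
    seed: int,
    n_exons: int = 5,
    n_group_a: int = 11,
    n_group_b: int = 13,
    n_controls: int = 5,
    n_predictors: int = 9,
    informativeness_probs: float | list[float] = 1.0,
    fp_prob: float = 0.2,
    separation_floor: float = 30.0,
    gene_id: str = "SYNTH1",
) -> SyntheticBundle:
    """Generate gene, variants and matrix from a single seeded stream."""
    rng = np.random.default_rng(seed)
    sequence, transcript = generate_gene(rng, n_exons=n_exons, gene_id=gene_id)
    variants = generate_variants(
        rng, transcript, n_group_a=n_group_a, n_group_b=n_group_b, n_controls=n_controls
    )
    matrix = generate_matrix(
        rng,
        variants,
        n_predictors=n_predictors,
        informativeness_probs=informativeness_probs,
        fp_prob=fp_prob,
        separation_floor=separation_floor,
    )
    params = {
        "seed": seed,
        "n_exons": n_exons,
        "n_group_a": n_group_a,
        "n_group_b": n_group_b,
        "n_controls": n_controls,
        "n_predictors": n_predictors,
        "fp_prob": fp_prob,
        "separation_floor": separation_floor,
        "gene_id": gene_id,
    }
    return SyntheticBundle(seed, sequence, transcript, variants, matrix, params)


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write FASTA + GFF3 + variants.tsv + matrix.tsv + manifest.txt."""
    from . import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "gene.fa",
        "gff3": directory / "gene.gff3",
        "variants": directory / "variants.tsv",
        "matrix": directory / "matrix.tsv",
        "manifest": directory / "manifest.txt",
    }
    try:
        sio.write_fasta(paths["fasta"], bundle.transcript.gene_id, bundle.sequence)
        sio.write_gff3(paths["gff3"], bundle.transcript)
        sio.write_variants_tsv(paths["variants"], bundle.variants)
        sio.write_matrix_tsv(paths["matrix"], bundle.matrix)
        lines = [f"{k}={v}" for k, v in sorted(bundle.params.items())]
        paths["manifest"].write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing bundle under {directory}: {exc}") from exc
    return paths


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Re-read a bundle written by :func:`write_bundle`."""
    from . import io as sio
    from .evaluation import PredictionMatrix

    directory = Path(directory)
    manifest = {}
    for line in (directory / "manifest.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            manifest[k] = v
    gene_id, sequence = sio.read_fasta(directory / "gene.fa")
    transcript = sio.read_gff3(directory / "gene.gff3", sequence=sequence)
    variants = sio.read_variants_tsv(directory / "variants.tsv")
    values = sio.read_matrix_tsv(directory / "matrix.tsv")
    matrix = PredictionMatrix(values=values, truth=variants["truth_spliceogenic"])
    params = {
        k: (int(v) if v.lstrip("-").isdigit() else (float(v) if _is_float(v) else v))
        for k, v in manifest.items()
    }
    return SyntheticBundle(
        seed=int(manifest["seed"]),
        sequence=sequence,
        transcript=transcript,
        variants=variants,
        matrix=matrix,
        params=params,
    )


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False
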