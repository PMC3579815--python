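"""Bundled BRCA1/BRCA2 splice-variant study tables.

The package ships, as plain TSV data, a published clinical series of 24
unclassified variants at BRCA1/BRCA2 splice sites: the variant descriptors
with their in vitro outcome (observed mRNA changes, allelic expression,
clinical class) and the variants x predictors percent-difference matrix for
the 13 group B variants across nine splice-prediction programs (SSF, MES,
NNSPLICE, GS, HSF, NG2, SV, SP, ASSA).  These tables are *inputs*: the
benchmark (threshold calibration, S/NS calls, false-positive rates) and the
protein-consequence annotations are recomputed from them by the package.

Exon structures of the two genes are provided as CDS-relative coordinate
maps (the classical U14680 / U43746 transcript framing; 5'UTRs are not
represented, and no variant in the series touches them).  Intron lengths
are placeholders -- only exon boundaries and splice-region offsets matter
for coordinate arithmetic on these tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import PredictionMatrix
from .transcript_consequences import (
    DELETION,
    EXON_SKIP,
    PARTIAL_LOSS,
    RETENTION,
    classify_rna_event,
    parse_hgvs_r,
)
from .transcripts import TranscriptModel

#: cDNA (CDS-relative) position of the last base of each exon.  BRCA1 keeps
#: the historical exon numbering gap (no exon 4); the first entry is the end
#: of the exon containing c.1.
BRCA1_EXON_ENDS = [
    80, 134, 212, 301, 441, 547, 593, 670, 4096, 4185, 4357, 4484, 4675,
    4986, 5074, 5152, 5193, 5277, 5332, 5406, 5467, 5592,
]
BRCA2_EXON_ENDS = [
    67, 316, 425, 475, 516, 631, 681, 793, 1909, 6841, 6937, 7007, 7435,
    7617, 7805, 7976, 8331, 8487, 8632, 8754, 8953, 9117, 9256, 9501, 9648,
    10257,
]

PREDICTORS = ["SSF", "MES", "NNSPLICE", "GS", "HSF", "NG2", "SV", "SP", "ASSA"]

#: consequence categories used in the study summary
CATEGORY_PTC = "aberrant_ptc_transcripts"
CATEGORY_ISOFORM = "isoform_up_regulation"
CATEGORY_INFRAME = "inframe_deletion"


def brca1_transcript() -> TranscriptModel:
    return TranscriptModel.from_cdna_exon_ends("BRCA1", BRCA1_EXON_ENDS)


def brca2_transcript() -> TranscriptModel:
    return TranscriptModel.from_cdna_exon_ends("BRCA2", BRCA2_EXON_ENDS)


def transcript_for(gene: str) -> TranscriptModel:
    if gene == "BRCA1":
        return brca1_transcript()
    if gene == "BRCA2":
        return brca2_transcript()
    raise KeyError(f"no bundled transcript for {gene!r}")


def _read_tsv(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("splicebench.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"], **kwargs)


def load_study_variants() -> pd.DataFrame:
    """The 24-variant series, indexed by HGVS c. descriptor."""
    df = _read_tsv("brca_splice_variants.tsv", index_col="hgvs_c")
    df["spliceogenic"] = df["spliceogenic"] == "yes"
    df["up_regulated_isoform"] = df["up_regulated_isoform"] == "yes"
    return df


def load_benchmark_matrix() -> PredictionMatrix:
    """Group B percent-difference matrix with in vitro truth labels."""
    values = _read_tsv("brca_group_b_predictions.tsv", index_col="hgvs_c").astype(float)
    variants = load_study_variants()
    truth = variants.loc[values.index, "spliceogenic"]
    return PredictionMatrix(values=values, truth=truth)


def _consequence_category(row: pd.Series) -> str:
    if row["up_regulated_isoform"]:
        return CATEGORY_ISOFORM
    change = parse_hgvs_r(row["mrna_change"])
    first = change.aberrant_events()[0]
    if first.net_length_change % 3 == 0 and first.kind == DELETION:
        return CATEGORY_INFRAME
    return CATEGORY_PTC


def _uses_alternative_site(row: pd.Series) -> bool:
    transcript = transcript_for(row["gene"])
    change = parse_hgvs_r(row["mrna_change"])
    return any(
        classify_rna_event(ev, transcript) in (PARTIAL_LOSS, RETENTION)
        for ev in change.aberrant_events()
    )


def summarize_study(variants: pd.DataFrame | None = None) -> dict:
    """Tallies over the series, recomputed from the mRNA-change descriptors.

    Counts spliceogenic variants, their consequence categories (aberrant
    PTC transcripts / up-regulated natural PTC isoform / in-frame deletion)
    and how many spliceogenic variants used an alternative (cryptic or
    novel) splice site, i.e. produced a partial exon loss or an intron
    retention.
    """
    if variants is None:
        variants = load_study_variants()
    spl = variants[variants["spliceogenic"]]
    categories = spl.apply(_consequence_category, axis=1)
    alt = spl.apply(_uses_alternative_site, axis=1)
    n_spl = int(len(spl))
    n_alt = int(alt.sum())
    return {
        "n_variants": int(len(variants)),
        "n_spliceogenic": n_spl,
        "n_ptc_transcripts": int((categories == CATEGORY_PTC).sum()),
        "n_isoform_up_regulation": int((categories == CATEGORY_ISOFORM).sum()),
        "n_inframe_deletion": int((categories == CATEGORY_INFRAME).sum()),
        "n_alternative_site_usage": n_alt,
        "alternative_site_pct": round(100.0 * n_alt / n_spl, 1) if n_spl else None,
    }
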