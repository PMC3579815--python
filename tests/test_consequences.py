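"""Protein-consequence prediction: frame arithmetic, codon numbering,
aberrant-mRNA assembly, translation against an independent oracle, allelic
proportions and clinical classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binomtest

from splicebench import (
    TranscriptModel,
    allelic_proportion,
    classify_clinical,
    classify_rna_event,
    mature_mrna,
    parse_hgvs_r,
    predict_consequence,
    predict_event_consequence,
)
from splicebench.datasets import summarize_study, transcript_for
from splicebench.transcript_consequences import (
    EXON_SKIP,
    FRAMESHIFT_PTC,
    INFRAME_DEL,
    NONSENSE,
    PARTIAL_LOSS,
    RETENTION,
    START_STOP_AFFECTED,
    RnaEvent,
    codon_number,
)

# -- codon arithmetic on the bundled clinical series -------------------------


@pytest.mark.parametrize(
    "gene, rchange, kind, codon",
    [
        ("BRCA1", "r.[380_441del]", FRAMESHIFT_PTC, 127),
        ("BRCA1", "r.[442_547del]", FRAMESHIFT_PTC, 148),
        ("BRCA1", "r.[4097g>a]", "substitution", 1366),
        ("BRCA1", "r.[5333a>g]", "substitution", 1778),
        ("BRCA2", "r.[9116c>u]", "substitution", 3039),
        ("BRCA1", "r.[4986_4987ins4986+1_4986+65;4986+1g>u]", FRAMESHIFT_PTC, 1663),
        ("BRCA2", "r.[517_631del]", FRAMESHIFT_PTC, 173),
    ],
)
def test_first_affected_codon_matches_reported_protein_changes(gene, rchange, kind, codon):
    (cons,) = predict_consequence(transcript_for(gene), parse_hgvs_r(rchange))
    assert cons.kind == kind
    assert cons.first_affected_codon == codon


def test_inframe_deletion_residue_count():
    # 51-nt loss at the 5' end of BRCA2 exon 23: 17 amino acids
    (cons,) = predict_consequence(transcript_for("BRCA2"), parse_hgvs_r("r.[8954_9004del]"))
    assert cons.kind == INFRAME_DEL
    assert cons.residues_deleted == 17
    assert cons.first_affected_codon == 2985


def test_codon_number_formula():
    assert [codon_number(c) for c in (1, 3, 4, 380, 4097)] == [1, 1, 2, 127, 1366]
    with pytest.raises(ValueError):
        codon_number(0)


@given(st.integers(4, 4000), st.integers(0, 500))
def test_frameshift_iff_span_not_multiple_of_three(start, extra):
    t = transcript_for("BRCA2")
    end = min(start + extra, t.cds_len - 3)
    if end < start:
        return
    ev = RnaEvent(kind="deletion", start=start, end=end)
    cons = predict_event_consequence(t, ev)
    if (end - start + 1) % 3 == 0:
        assert cons.kind in (INFRAME_DEL, NONSENSE)
    else:
        assert cons.kind == FRAMESHIFT_PTC


def test_change_touching_cds_ends_is_flagged():
    t = transcript_for("BRCA1")
    assert predict_event_consequence(t, RnaEvent(kind="deletion", start=1, end=10)).kind \
        == START_STOP_AFFECTED
    assert predict_event_consequence(
        t, RnaEvent(kind="deletion", start=t.cds_len - 5, end=t.cds_len)
    ).kind == START_STOP_AFFECTED


# -- event refinement against exon structure ---------------------------------


@pytest.mark.parametrize(
    "gene, rchange, kinds",
    [
        ("BRCA1", "r.[81_134del]", [EXON_SKIP]),  # whole exon
        ("BRCA1", "r.[191_212del]", [PARTIAL_LOSS]),  # 3' partial
        ("BRCA1", "r.[5278_5332del,5278_5285del]", [EXON_SKIP, PARTIAL_LOSS]),
        ("BRCA2", "r.[426_516del]", [EXON_SKIP]),  # two consecutive exons
        ("BRCA2", "r.[8754_8755ins8754+1_8754+46;8754+4a>g]", [RETENTION]),
    ],
)
def test_deletions_refined_to_skip_or_partial(gene, rchange, kinds):
    t = transcript_for(gene)
    change = parse_hgvs_r(rchange)
    assert [classify_rna_event(e, t) for e in change.aberrant_events()] == kinds


def test_study_summary_tallies():
    s = summarize_study()
    assert s["n_spliceogenic"] == 19
    assert s["n_ptc_transcripts"] == 16
    assert s["n_isoform_up_regulation"] == 2
    assert s["n_inframe_deletion"] == 1
    assert s["n_alternative_site_usage"] == 10


# -- aberrant mRNA assembly --------------------------------------------------


def _toy_transcript():
    # two 12-nt exons around a 20-nt intron; CDS = whole mature mRNA
    exon1 = "ATGGCTGCAGCA"
    intron = "GTAAGTCCCCCCCCCCCCAG"
    exon2 = "GCAGCAGCATAA"
    seq = exon1 + intron + exon2
    return TranscriptModel("TOY", [(0, 12), (32, 44)], sequence=seq)


def test_mature_mrna_identity_without_events():
    t = _toy_transcript()
    seq, pos_map = mature_mrna(t, parse_hgvs_r("r.[=]"))
    assert seq == t.cds_sequence()
    assert pos_map == {i: i for i in range(1, 25)}


def test_exon_skip_shortens_by_exon_length(small_gene):
    _, t = small_gene
    lo, hi = t.exon_cdna_bounds()[2]
    seq, _ = mature_mrna(t, RnaEvent(kind="deletion", start=lo, end=hi))
    assert len(seq) == t.cds_len - (hi - lo + 1)


def test_retention_inserts_intron_and_shifts_codon_map():
    t = _toy_transcript()
    ev = RnaEvent(
        kind=RETENTION, after_pos=12, retained_len=20, intron_anchors=(12, 1, 12, 20)
    )
    seq, pos_map = mature_mrna(t, ev)
    assert len(seq) == 24 + 20
    assert seq[12:32] == "GTAAGTCCCCCCCCCCCCAG"
    for p in range(1, 13):
        assert pos_map[p] == p
    for p in range(13, 25):
        assert pos_map[p] == p + 20  # downstream bases shift by the retained span


def test_overlapping_events_rejected():
    t = _toy_transcript()
    change = parse_hgvs_r("r.[2_10del,5_12del]")
    with pytest.raises(ValueError, match="overlapping"):
        mature_mrna(t, change)


# -- translation oracle ------------------------------------------------------

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_SENSE = [c for c, aa in _CODONS.items() if aa != "*"]


def _oracle_translate(seq):
    return "".join(_CODONS[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def _oracle_first_stop(protein):
    k = protein.find("*")
    return k + 1 if k >= 0 else None


def test_consequence_matches_translation_oracle_on_random_transcripts():
    """Frame status and premature-stop location agree with brute-force
    apply-translate-scan on >= 1000 random single-exon transcripts."""
    rng = np.random.default_rng(77)
    n_cases = 0
    for _ in range(260):
        m = int(rng.integers(10, 60))
        cds = "ATG" + "".join(rng.choice(_SENSE) for _ in range(m)) + "TAA"
        t = TranscriptModel("R", [(0, len(cds))], sequence=cds)
        events = []
        for _ in range(2):  # deletions
            s = int(rng.integers(4, len(cds) - 4))
            e = int(rng.integers(s, len(cds) - 3))
            events.append(RnaEvent(kind="deletion", start=s, end=e))
        for _ in range(2):  # substitutions
            p = int(rng.integers(4, len(cds) - 3))
            alt = "ACGT"[int(rng.integers(0, 4))]
            events.append(RnaEvent(kind="substitution", start=p, end=p, ref=cds[p - 1].lower(), alt=alt.lower()))
        for ev in events:
            cons = predict_event_consequence(t, ev)
            if ev.kind == "deletion":
                aberrant = cds[: ev.start - 1] + cds[ev.end :]
            else:
                aberrant = cds[: ev.start - 1] + ev.alt.upper() + cds[ev.start :]
            protein = _oracle_translate(aberrant)
            stop = _oracle_first_stop(protein)
            n = ev.end - ev.start + 1 if ev.kind == "deletion" else 0
            if ev.kind == "deletion" and n % 3 != 0:
                assert cons.kind == FRAMESHIFT_PTC
                assert cons.ptc_codon == stop
            elif ev.kind == "deletion":
                premature = stop is not None and stop != len(protein)
                assert cons.kind == (NONSENSE if premature else INFRAME_DEL)
                if premature:
                    assert cons.ptc_codon == stop
            else:
                wt_aa = _oracle_translate(cds)[cons.first_affected_codon - 1]
                mut_aa = protein[cons.first_affected_codon - 1]
                expected = (
                    "silent" if mut_aa == wt_aa
                    else NONSENSE if mut_aa == "*"
                    else "missense"
                )
                assert cons.kind == expected
            n_cases += 1
    assert n_cases >= 1000


def test_retention_consequence_matches_oracle(small_gene):
    seq, t = small_gene
    rng = np.random.default_rng(5)
    bounds = t.exon_cdna_bounds()
    for i in range(t.n_exons - 1):
        after = bounds[i][1]
        length = int(rng.integers(4, 60))
        ev = RnaEvent(
            kind=RETENTION, after_pos=after, retained_len=length,
            intron_anchors=(after, 1, after, length),
        )
        cons = predict_event_consequence(t, ev)
        intron = t.intron_sequence(i)
        aberrant = t.cds_sequence()[:after] + intron[:length] + t.cds_sequence()[after:]
        stop = _oracle_first_stop(_oracle_translate(aberrant))
        if length % 3 != 0:
            assert cons.kind == FRAMESHIFT_PTC
            assert cons.ptc_codon == stop
        assert cons.first_affected_codon == after // 3 + 1


# -- allelic proportions and clinical class ----------------------------------


def test_allelic_proportion_reported_values():
    assert allelic_proportion(20, 23).percent == 87
    assert allelic_proportion(47, 52).percent == 90
    assert allelic_proportion(0, 10).percent == 0
    with pytest.raises(ValueError):
        allelic_proportion(1, 0)


def test_allelic_ci_matches_independent_exact_method():
    for k, n in [(20, 23), (47, 52), (0, 10), (5, 5)]:
        res = allelic_proportion(k, n)
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        assert res.ci_low == pytest.approx(ci.low, abs=1e-9)
        assert res.ci_high == pytest.approx(ci.high, abs=1e-9)


@pytest.mark.parametrize(
    "spliceogenic, expr, prior, intronic, expected",
    [
        (True, "mono", None, False, "5"),
        (True, "bi", None, False, "4"),
        (True, "not_assessable", None, False, "4 or 5"),
        (False, "bi", True, False, "2"),
        (False, "bi", None, True, "2"),
        (False, "bi", None, False, "unclassified"),
    ],
)
def test_clinical_classification(spliceogenic, expr, prior, intronic, expected):
    assert classify_clinical(spliceogenic, expr, prior, intronic) == expected
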