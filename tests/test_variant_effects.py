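"""Variant application, percent-difference formulas, alternative-site scans,
and splice-region group assignment."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicebench import (
    apply_variant,
    assign_group,
    delta_for_site,
    find_alternative_sites,
    parse_hgvs_c,
    percent_diff_ri,
    percent_diff_ssps,
)
from splicebench.datasets import transcript_for
from splicebench.splice_models import BASES
from splicebench.variant_effects import map_position_through_edit

# -- apply_variant -----------------------------------------------------------


@pytest.mark.parametrize(
    "span, ref, alt, expected",
    [
        ((2, 3), "G", "T", "ACTTACGT"),  # SNV at 1-based position 3
        ((1, 3), "CG", "", "ATACGT"),  # deletion of positions 2-3
        ((1, 3), "CG", "AA", "AAATACGT"),  # delins
    ],
)
def test_apply_variant_examples(span, ref, alt, expected):
    assert apply_variant("ACGTACGT", *span, ref, alt) == expected


def test_apply_variant_reference_mismatch_names_alleles():
    with pytest.raises(ValueError, match="expected 'A', observed 'C'"):
        apply_variant("ACGT", 1, 2, "A", "G")


def test_apply_variant_out_of_bounds():
    with pytest.raises(ValueError, match="out of bounds"):
        apply_variant("ACGT", 2, 9, "", "")


@given(st.text(alphabet="ACGT", min_size=5, max_size=60), st.data())
def test_snv_apply_then_revert_is_identity(seq, data):
    pos = data.draw(st.integers(0, len(seq) - 1))
    alt = data.draw(st.sampled_from("ACGT"))
    mutated = apply_variant(seq, pos, pos + 1, seq[pos], alt)
    assert apply_variant(mutated, pos, pos + 1, alt, seq[pos]) == seq


# -- percent differences -----------------------------------------------------


def test_percent_diff_ssps_examples():
    assert percent_diff_ssps(10, 0) == pytest.approx(-100.0)
    assert percent_diff_ssps(7.3, 7.3) == pytest.approx(0.0)
    assert percent_diff_ssps(8.5, 5.1) == pytest.approx(-40.0)


def test_percent_diff_ssps_requires_recognized_wt():
    with pytest.raises(ValueError, match="not recognized in wild type"):
        percent_diff_ssps(0.0, 5.0)


@given(
    st.floats(0.1, 100),
    st.floats(0, 100),
    st.floats(0, 100),
)
def test_percent_diff_ssps_monotone_in_mut(wt, m1, m2):
    lo, hi = sorted((m1, m2))
    assert percent_diff_ssps(wt, lo) <= percent_diff_ssps(wt, hi)


def test_percent_diff_ri_bit_scale():
    assert percent_diff_ri(5.0, 6.0) == 100.0  # +1 bit doubles affinity, exactly
    assert percent_diff_ri(5.0, 5.0) == 0.0
    assert percent_diff_ri(5.0, 4.0) == pytest.approx(-50.0)


def test_percent_diff_ri_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        percent_diff_ri(float("nan"), 1.0)


@given(st.floats(-30, 30), st.floats(-30, 30))
def test_percent_diff_ri_bounds_and_sign(wt, mut):
    pct = percent_diff_ri(wt, mut)
    assert pct > -100.0
    assert math.copysign(1, pct) == math.copysign(1, mut - wt) or pct == 0


# -- delta at the natural site ----------------------------------------------


def test_delta_zero_for_variant_outside_window(donor_model, small_gene):
    seq, transcript = small_gene
    j = transcript.donor_junctions()[0]
    pos = j + 50  # deep intronic, outside the -3..+6 window
    res = delta_for_site(
        donor_model, seq, pos, pos + 1, seq[pos], "A" if seq[pos] != "A" else "C",
        natural_site=j, scorer="cv", floor=0.0,
    )
    assert res.informative
    assert res.percent_diff == pytest.approx(0.0)


def test_delta_invariant_dinucleotide_hit_decreases_score(donor_model, small_gene):
    seq, transcript = small_gene
    for scorer in ("cv", "ri"):
        for j in transcript.donor_junctions():
            assert seq[j] == "G"
            res = delta_for_site(
                donor_model, seq, j, j + 1, "G", "T",
                natural_site=j, scorer=scorer, floor=-1e9,
            )
            assert res.mut_score < res.wt_score
            assert res.percent_diff < 0


def test_delta_non_informative_below_floor(donor_model):
    seq = "C" * 60  # scores far below any reasonable floor
    res = delta_for_site(
        donor_model, seq, 30, 31, "C", "A", natural_site=30, scorer="cv", floor=70.0
    )
    assert not res.informative
    assert res.percent_diff is None and res.mut_score is None


# -- alternative-site detection ----------------------------------------------


def test_unmutated_sequence_yields_only_cryptic_tags(donor_model, rng):
    seq = "".join(rng.choice(list(BASES), size=1500))
    sites = find_alternative_sites(
        donor_model, seq, seq, natural_site=700, floor=40.0, scorer="cv"
    )
    assert sites  # random 1.5 kb contains sites above a low floor
    assert all(s.tag == "cryptic" for s in sites)
    assert all(s.position != 700 for s in sites)


def test_variant_created_site_tagged_novel(donor_model):
    best = "".join(BASES[i] for i in donor_model.freqs.argmax(axis=1))
    # background free of G and T: no donor-like site can pre-exist
    wt = "CA" * 300
    start, end = 400, 400 + len(best)
    mut = apply_variant(wt, start, end, wt[start:end], best)
    sites = find_alternative_sites(
        donor_model, wt, mut,
        natural_site=100, span_start=start, span_end=end, alt_len=len(best),
        floor=99.0, scorer="cv",
    )
    assert [s.tag for s in sites] == ["novel"]
    assert sites[0].position == start + donor_model.window.exonic


def test_cryptic_intronic_site_found_after_natural_donor_ablated(donor_model, small_gene):
    seq, transcript = small_gene
    j = transcript.donor_junctions()[1]
    # plant a strong donor 65 bp into the intron (cryptic: present in wt too)
    best = "".join(BASES[i] for i in donor_model.freqs.argmax(axis=1))
    planted_start = j + 65 - donor_model.window.exonic
    wt = seq[:planted_start] + best + seq[planted_start + len(best):]
    # the variant destroys the natural GT
    mut = apply_variant(wt, j, j + 1, "G", "T")
    sites = find_alternative_sites(
        donor_model, wt, mut, natural_site=j,
        span_start=j, span_end=j + 1, alt_len=1,
        floor=99.0, scorer="cv",
    )
    by_distance = {s.distance: s.tag for s in sites}
    assert by_distance.get(65) == "cryptic"


def test_no_candidate_above_floor_gives_empty_list(donor_model):
    seq = "CA" * 400
    assert (
        find_alternative_sites(donor_model, seq, seq, natural_site=400, floor=50.0)
        == []
    )


def test_coordinate_mapping_through_edit():
    # 3-base deletion: downstream shifts left, inside clamps
    assert map_position_through_edit(10, 20, 23, 0) == 10
    assert map_position_through_edit(30, 20, 23, 0) == 27
    assert map_position_through_edit(21, 20, 23, 0) == 20
    # insertion of 2
    assert map_position_through_edit(30, 20, 20, 2) == 32


# -- group assignment --------------------------------------------------------


@pytest.mark.parametrize(
    "hgvs, gene, expected",
    [
        ("c.441+2T>G", "BRCA1", "A"),
        ("c.5278-2delA", "BRCA1", "A"),
        ("c.8954-1_8955delGTTinsAA", "BRCA2", "A"),
        ("c.213-11T>G", "BRCA1", "B"),
        ("c.134+3_134+6delAAGT", "BRCA1", "B"),
        ("c.212G>A", "BRCA1", "B"),  # last exonic base, donor side
        ("c.4097G>A", "BRCA1", "B"),  # first exonic base, acceptor side
        ("c.4000G>A", "BRCA1", "other"),  # deep exonic
        ("c.441+30T>G", "BRCA1", "other"),  # deep intronic
    ],
)
def test_assign_group_on_reference_variants(hgvs, gene, expected):
    assert assign_group(parse_hgvs_c(hgvs), transcript_for(gene)) == expected


def test_group_footprints_exhaustive_around_boundaries(small_gene):
    """Walk every position within +/-15 nt of a donor and an acceptor
    boundary; A and B footprints must match their definitions and never
    overlap."""
    seq, transcript = small_gene
    donor_j = transcript.donor_junctions()[1]
    acceptor_j = transcript.acceptor_junctions()[1]
    for g in range(donor_j - 15, donor_j + 15):
        anchor, offset = transcript.gene_local_to_cdna(g)
        hgvs = f"c.{anchor}{offset:+d}" if offset else f"c.{anchor}"
        v = parse_hgvs_c(f"{hgvs}{seq[g]}>{'A' if seq[g] != 'A' else 'C'}")
        got = assign_group(v, transcript)
        if 0 < offset <= 2:
            expected = "A"
        elif 3 <= offset <= 8 or (offset == 0 and donor_j - g <= 3):
            expected = "B"
        else:
            expected = "other"
        assert got == expected, (g, offset)
    for g in range(acceptor_j - 15, acceptor_j + 15):
        anchor, offset = transcript.gene_local_to_cdna(g)
        hgvs = f"c.{anchor}{offset:+d}" if offset else f"c.{anchor}"
        v = parse_hgvs_c(f"{hgvs}{seq[g]}>{'A' if seq[g] != 'A' else 'C'}")
        got = assign_group(v, transcript)
        if -2 <= offset < 0:
            expected = "A"
        elif -12 <= offset <= -3 or (offset == 0 and g - acceptor_j <= 1):
            expected = "B"
        else:
            expected = "other"
        assert got == expected, (g, offset)
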