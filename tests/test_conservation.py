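"""Ortholog conservation statistics: tallies, binomial null, tables."""

import numpy as np
import pytest

from phoskit.conservation import (CenterColumn, OrthologConservation,
                                  StateCounts, UndefinedStatisticError,
                                  chi_square, composition_from_counts,
                                  composition_table,
                                  conditional_probabilities,
                                  disorder_histogram, expected_counts,
                                  extract_center_columns, ground_probability,
                                  pfm, similarity_profile, tally_states)
from phoskit.io import AMINO_ACIDS, OrthoGroupRecord

ST_COUNTS = StateCounts("ST", (291, 156, 82, 102))
Y_COUNTS = StateCounts("Y", (110, 50, 25, 15))


def _col(residues, flags, gid="g", column=5):
    from phoskit.conservation import _classify
    return CenterColumn(group_id=gid, column=column, residues=tuple(residues),
                        gap_flags=tuple(r == "-" for r in residues),
                        phospho_flags=tuple(flags),
                        center_class=_classify(residues))


def _quartet(seqs, gid="g1", organisms=("a", "b", "c", "d")):
    return OrthoGroupRecord(group_id=gid,
                            members=list(zip(organisms, seqs)))


# ---------------------------------------------------------------------------
# Column extraction

def test_extract_center_columns_classes():
    g = _quartet(["AASAA"] * 4)
    cols = extract_center_columns(g, {})
    assert len(cols) == 1
    assert cols[0].center_class == "ST_pure"
    assert cols[0].phospho_flags == (False,) * 4

    g = _quartet(["AASAA", "AASAA", "AATAA", "AASAA"])
    assert extract_center_columns(g, {})[0].center_class == "ST_pure"

    g = _quartet(["AASAA", "AASAA", "AAYAA", "AASAA"])
    assert extract_center_columns(g, {})[0].center_class == "other"


def test_extract_center_columns_maps_through_gaps():
    # member b has a gap before its center: aligned column 3 is its
    # unaligned position 3
    g = _quartet(["AAASA", "A-ASA", "AAASA", "AAASA"])
    flags = {("g1|b", 3): True}
    col = [c for c in extract_center_columns(g, flags) if c.column == 3][0]
    assert col.phospho_flags == (False, True, False, False)


def test_gapped_member_never_phosphorylated():
    g = _quartet(["AASAA", "AA-AA", "AASAA", "AASAA"])
    cols = extract_center_columns(g, {("g1|b", 3): True})
    assert cols[0].gap_flags == (False, True, False, False)
    assert cols[0].phospho_flags[1] is False


# ---------------------------------------------------------------------------
# Tallies

def test_tally_states_counts_by_phospho_number():
    cols = [_col("SSSS", [True, False, False, False], gid=f"g{i}")
            for i in range(3)]
    counts = tally_states(cols, "ST")
    assert counts.n == (3, 0, 0, 0)
    assert counts.N == 3


def test_tally_excludes_zero_flag_and_wrong_class():
    cols = [_col("SSSS", [False] * 4),            # zero flags: excluded
            _col("YYYY", [True] * 4),             # Y-pure: not ST
            _col("STST", [True, True, False, False])]
    assert tally_states(cols, "ST").n == (0, 1, 0, 0)
    assert tally_states(cols, "Y").n == (0, 0, 0, 1)


def test_published_fixture_totals():
    assert ST_COUNTS.N == 631
    assert Y_COUNTS.N == 200


# ---------------------------------------------------------------------------
# Ground probability, expectations, chi-square

def test_ground_probability_fixtures():
    assert ground_probability(ST_COUNTS) == pytest.approx(0.331, abs=5e-4)
    assert ground_probability(Y_COUNTS) == pytest.approx(0.242, abs=5e-4)
    assert ground_probability(StateCounts("ST", (7, 0, 0, 0))) == 0.0


def test_expected_counts_fixtures():
    st = np.round(expected_counts(ST_COUNTS)).astype(int)
    assert list(st) == [189, 280, 139, 23]
    y = np.round(expected_counts(Y_COUNTS)).astype(int)
    assert list(y) == [87, 83, 27, 3]


def test_expected_counts_degenerate_and_sum():
    e = expected_counts(StateCounts("ST", (5, 0, 0, 0)), p=0.0)
    np.testing.assert_allclose(e, [5, 0, 0, 0])
    for counts in (ST_COUNTS, Y_COUNTS):
        assert expected_counts(counts).sum() == pytest.approx(counts.N,
                                                              abs=1e-9)


def test_chi_square_identity_and_hand_case():
    chi2, p = chi_square([189, 280, 139, 23], [189, 280, 139, 23])
    assert chi2 == 0.0 and p == 1.0
    chi2, _ = chi_square([10, 20, 30, 40], [25, 25, 25, 25])
    assert chi2 == pytest.approx(20.0)
    with pytest.raises(ValueError, match="positive"):
        chi_square([1, 2, 3, 4], [1, 2, 3, 0])


def test_conditional_probabilities_fixtures():
    p2, p3, p4 = conditional_probabilities(ST_COUNTS)
    assert (round(p2, 3), round(p3, 3), round(p4, 3)) == (0.331, 0.421, 0.554)
    assert conditional_probabilities(Y_COUNTS)[2] == pytest.approx(0.375)
    # the alternative upper-stratum formula for p3
    assert conditional_probabilities(Y_COUNTS, p3_method="upper")[1] == \
        pytest.approx(0.688, abs=5e-4)


def test_conditional_probabilities_edge_cases():
    p2, p3, p4 = conditional_probabilities(StateCounts("ST", (0, 0, 0, 9)))
    assert p3 == 1.0 and p4 == 1.0
    with pytest.raises(UndefinedStatisticError):
        conditional_probabilities(StateCounts("ST", (5, 0, 0, 0)))


def test_results_object_summary():
    res = OrthologConservation(ST_COUNTS).fit()
    text = res.summary()
    assert "0.331" in text and "0.554" in text
    d = res.to_dict()
    assert d["observed"] == [291, 156, 82, 102]
    assert d["df"] == 3


# ---------------------------------------------------------------------------
# Composition table

def test_composition_table_published_fixture():
    table = composition_from_counts((6639, 1477, 1002, 2099, 9318),
                                    (9, 4, 3, 7, 79))
    np.testing.assert_allclose(
        [table["non_phosphorylated"][k]
         for k in ("4T", "1S3T", "2S2T", "3S1T", "4S")],
        [32.33, 7.19, 4.88, 10.22, 45.38], atol=5e-3)
    assert table["fully_conserved"]["4S"] == pytest.approx(77.45, abs=5e-3)
    for stratum in table.frequencies.values():
        assert sum(stratum.values()) == pytest.approx(100.0, abs=1e-9)


def test_composition_table_from_columns():
    cols = [_col("SSSS", [True] * 4),
            _col("STST", [False] * 4),
            _col("SSSS", [True, True, False, False])]  # partial: ignored
    table = composition_table(cols)
    assert table["fully_conserved"]["4S"] == 100.0
    assert table["non_phosphorylated"]["2S2T"] == 100.0


def test_composition_empty_stratum_warns():
    with pytest.warns(UserWarning, match="empty stratum"):
        table = composition_table([_col("SSSS", [True] * 4)])
    assert sum(table.counts["non_phosphorylated"].values()) == 0


# ---------------------------------------------------------------------------
# Similarity profile, disorder histogram, PFM

def test_similarity_profile_identical_sequences():
    g = _quartet(["ACDEFSAGHIK"] * 4)
    cols = extract_center_columns(g, {(f"g1|{o}", 6): True
                                      for o in "abcd"})
    center = [c for c in cols if c.residues == ("S",) * 4][0]
    prof = similarity_profile([center], {"g1": g}, flank=5)
    np.testing.assert_allclose(prof.mean, 1.0)
    np.testing.assert_allclose(prof.sd, 0.0)


def test_similarity_profile_two_identical_pairs():
    g = _quartet(["AAAAASAAAAA", "AAAAASAAAAA",
                  "CCCCCSCCCCC", "CCCCCSCCCCC"])
    flags = {(f"g1|{o}", 6): True for o in "abcd"}
    center = extract_center_columns(g, flags)[0]
    prof = similarity_profile([center], {"g1": g}, flank=5)
    np.testing.assert_allclose(prof.mean, 2.0 / 6.0)


def test_similarity_profile_random_background(rng):
    """Uniform random symbols: expected pair identity is 1/20."""
    groups, cols = {}, []
    for i in range(400):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=11))
                for _ in range(4)]
        for s in range(4):
            seqs[s] = seqs[s][:5] + "S" + seqs[s][6:]
        g = _quartet(seqs, gid=f"g{i}")
        groups[f"g{i}"] = g
        cols.append(_col("SSSS", [True] * 4, gid=f"g{i}", column=5))
    prof = similarity_profile(cols, groups, flank=5)
    assert prof.n_groups == 400
    assert prof.mean.mean() == pytest.approx(0.05, abs=0.01)


def test_disorder_histogram_properties(rng):
    density, edges = disorder_histogram(rng.uniform(size=500), bins=20)
    widths = np.diff(edges)
    assert (density * widths).sum() == pytest.approx(1.0, abs=1e-9)
    density, edges = disorder_histogram([0.5] * 50, bins=10)
    assert (density > 0).sum() == 1


def test_pfm_gap_free_counting():
    g1 = _quartet(["ACDEFSAGHIK"] * 4, gid="g1")
    c1 = _col("SSSS", [True] * 4, gid="g1", column=5)
    matrix = pfm([c1], {"g1": g1}, flank=3)
    assert matrix.n_groups == 1
    # identical members: one residue per column with count 4
    assert np.all(matrix.counts.sum(axis=0) == 4)
    assert np.all((matrix.counts > 0).sum(axis=0) == 1)

    # a gap inside the window excludes the whole group
    g2 = _quartet(["ACDEFSAG-IK", "ACDEFSAGHIK",
                   "ACDEFSAGHIK", "ACDEFSAGHIK"], gid="g2")
    c2 = _col("SSSS", [True] * 4, gid="g2", column=5)
    matrix = pfm([c1, c2], {"g1": g1, "g2": g2}, flank=3)
    assert matrix.n_groups == 1

    # column sums are uniform across positions
    matrix = pfm([c1, c1], {"g1": g1}, flank=2)
    assert len(set(matrix.counts.sum(axis=0))) == 1
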