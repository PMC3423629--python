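"""KNN scores, disorder profiles and composition features."""

import numpy as np
import pytest

from phoskit import features as F
from phoskit.features import (aa_frequency, blosum_similarity,
                              builtin_disorder_profile, disorder_features,
                              featurize, knn_scores, knn_scores_batch,
                              DisorderProfile)
from phoskit.io import AMINO_ACIDS, PeptideWindow


def _win(flank, label="unknown", pid="p", pos=1):
    h = (len(flank) - 1) // 2
    return PeptideWindow(protein_id=pid, position=pos, center=flank[h],
                         flank=flank, label=label)


def _random_windows(rng, n, length=13, pid="t"):
    wins = []
    for i in range(n):
        chars = rng.choice(list(AMINO_ACIDS), size=length)
        chars[length // 2] = rng.choice(list("STY"))
        label = "positive" if rng.uniform() < 0.5 else "negative"
        wins.append(_win("".join(chars), label, pid=pid, pos=i + 1))
    return wins


# ---------------------------------------------------------------------------
# BLOSUM similarity

def test_blosum_similarity_examples():
    assert blosum_similarity("SSS", "SSS") == 12  # 3 x BLOSUM62(S,S)=4
    assert blosum_similarity("S--", "S--") == 4   # pads contribute 0
    assert blosum_similarity("SXS", "SSS") == 8   # X contributes 0
    with pytest.raises(ValueError):
        blosum_similarity("SS", "SSS")


def test_blosum_self_similarity_dominates(rng):
    """Self-similarity is at least the similarity to any other window."""
    for _ in range(50):
        a = "".join(rng.choice(list(AMINO_ACIDS), size=9))
        b = "".join(rng.choice(list(AMINO_ACIDS), size=9))
        assert blosum_similarity(a, a) >= blosum_similarity(a, b)


# ---------------------------------------------------------------------------
# KNN scores vs brute-force oracle

def _oracle_knn(query, training, fractions, exclude_self):
    """Exhaustive-sort reference implementation, independent of the
    vectorized path: explicit pairwise scoring and a full stable sort."""
    pool = [(i, w) for i, w in enumerate(training)
            if not (exclude_self and w.key == query.key)]
    sims = [(-blosum_similarity(query.flank, w.flank), i, w.label)
            for i, w in pool]
    sims.sort()  # ascending in -similarity; index breaks ties
    n = len(sims)
    out = []
    for f in fractions:
        k = max(1, int(np.floor(f * n + 0.5)))
        out.append(sum(1 for s in sims[:k] if s[2] == "positive") / k)
    return np.array(out)


@pytest.mark.parametrize("n_train", [1, 5, 17, 50, 101, 200])
@pytest.mark.parametrize("exclude_self", [False, True])
def test_knn_matches_oracle(n_train, exclude_self):
    rng = np.random.default_rng(100 + n_train)
    training = _random_windows(rng, n_train)
    queries = _random_windows(rng, 8, pid="q")
    if exclude_self:
        if n_train < 2:
            pytest.skip("self-exclusion needs >= 2 training windows")
        queries[0] = training[0]  # one query identical to a training window
    got = knn_scores_batch(queries, training, F.KNN_FRACTIONS + (0.5, 1.0),
                           exclude_self=exclude_self)
    for qi, q in enumerate(queries):
        expected = _oracle_knn(q, training, F.KNN_FRACTIONS + (0.5, 1.0),
                               exclude_self)
        np.testing.assert_allclose(got[qi], expected, err_msg=f"query {qi}")


def test_knn_trivial_cases():
    q = _win("AAASAA" + "SAAAAAA"[:7], pid="q", pos=9)
    pos = _win(q.flank, "positive", pid="t", pos=1)
    assert knn_scores(q, [pos], fractions=[1.0])[0] == 1.0
    # symmetric tie: equal positives and negatives at identical similarity
    ties = [_win("AAAAAASAAAAAA", "positive", pos=i) for i in range(1, 4)] + \
           [_win("AAAAAASAAAAAA", "negative", pos=i) for i in range(4, 7)]
    assert knn_scores(q, ties, fractions=[1.0])[0] == 0.5
    with pytest.raises(ValueError):
        knn_scores(q, [], fractions=[1.0])


def test_knn_invariant_to_training_order_except_ties(rng):
    """Reordering the training set only matters through tie-breaking; the
    oracle with the permuted order must agree with the implementation."""
    training = _random_windows(rng, 40)
    queries = _random_windows(rng, 5, pid="q")
    permuted = training[::-1]
    got = knn_scores_batch(queries, permuted)
    for qi, q in enumerate(queries):
        np.testing.assert_allclose(
            got[qi], _oracle_knn(q, permuted, F.KNN_FRACTIONS, False))
    # at f=1.0 every window is a neighbor, so order cannot matter at all
    np.testing.assert_allclose(
        knn_scores_batch(queries, training, fractions=(1.0,)),
        knn_scores_batch(queries, permuted, fractions=(1.0,)))


# ---------------------------------------------------------------------------
# Disorder

def test_builtin_disorder_endpoints():
    np.testing.assert_allclose(builtin_disorder_profile("P" * 30).scores,
                               1.0, atol=1e-12)
    np.testing.assert_allclose(builtin_disorder_profile("W" * 30).scores,
                               0.0, atol=1e-12)


def test_builtin_disorder_reversal_symmetry(rng):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=80))
    fwd = builtin_disorder_profile(seq).scores
    rev = builtin_disorder_profile(seq[::-1]).scores
    np.testing.assert_allclose(fwd, rev[::-1])


def test_builtin_disorder_ranks_known_contexts():
    """Ser/Pro-rich low-complexity scores above aromatic/hydrophobic."""
    disordered = builtin_disorder_profile("SPSPESKPSPSES").scores.mean()
    ordered = builtin_disorder_profile("WFIVLWFIVLWFI").scores.mean()
    assert disordered > ordered


def test_disorder_features_examples():
    prof = DisorderProfile(protein_id="p", scores=np.full(20, 0.7))
    np.testing.assert_allclose(disorder_features(prof, 10), [0.7, 0.7, 0.7])
    ramp = DisorderProfile(protein_id="p", scores=np.linspace(0, 1, 11))
    # w=1 is exactly the site's own score
    assert disorder_features(ramp, 4)[0] == ramp.scores[3]
    # boundary clipping: site 1, w=5 averages positions 1..3 only
    np.testing.assert_allclose(disorder_features(ramp, 1, windows=(5,)),
                               [ramp.scores[:3].mean()])


def test_disorder_features_monotone(rng):
    scores = rng.uniform(size=50)
    prof_lo = DisorderProfile(protein_id="p", scores=scores)
    prof_hi = DisorderProfile(protein_id="p",
                              scores=np.clip(scores + 0.1, 0, 1))
    for pos in (1, 10, 25, 50):
        assert np.all(disorder_features(prof_hi, pos)
                      >= disorder_features(prof_lo, pos))


# ---------------------------------------------------------------------------
# Composition

def test_aa_frequency_examples():
    f = aa_frequency("SSSSSSSSSSSSS")
    assert f[AMINO_ACIDS.index("S")] == 1.0
    assert f.sum() == 1.0
    f = aa_frequency("------SAAAA--")
    assert f[AMINO_ACIDS.index("S")] == pytest.approx(0.2)
    assert f[AMINO_ACIDS.index("A")] == pytest.approx(0.8)
    with pytest.raises(ValueError):
        aa_frequency("-------------")


def test_aa_frequency_normalizes(rng):
    for _ in range(20):
        w = "".join(rng.choice(list(AMINO_ACIDS + "-X"), size=13))
        if set(w) <= {"-", "X"}:
            continue
        assert aa_frequency(w).sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Assembly

def test_featurize_orders_families(rng):
    training = _random_windows(rng, 30)
    prof = DisorderProfile(protein_id="q", scores=rng.uniform(size=40))
    q = _win("AAAAAATAAAAAA", pid="q", pos=20)
    v = featurize(q, training, prof)
    assert v.shape == (F.N_FEATURES,)
    np.testing.assert_allclose(v[:5], knn_scores(q, training))
    np.testing.assert_allclose(v[5:8], disorder_features(prof, 20))
    np.testing.assert_allclose(v[8:], aa_frequency(q))
    assert np.isfinite(v).all()
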