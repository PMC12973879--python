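"""Rank tests, BH-FDR, the LEfSe-style screen, and PERMANOVA."""

import numpy as np
import pytest

from enterokit import (bh_fdr, kruskal_wallis, lefse_screen, permanova,
                       rank_sum_test, pairwise_distances)
from enterokit.distance import DistanceMatrix
from enterokit.io import ValidationError
from enterokit.stats import kruskal_wallis_features

from conftest import make_table, random_compositions


def test_rank_sum_exact_small():
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert res["U"] == 0.0
    assert res["p"] == pytest.approx(0.1, abs=1e-12)


def test_rank_sum_identical_and_symmetric(rng):
    x = rng.normal(size=8)
    assert rank_sum_test(x, x)["p"] == pytest.approx(1.0, abs=1e-9)
    y = rng.normal(size=10)
    assert rank_sum_test(x, y)["p"] == pytest.approx(
        rank_sum_test(y, x)["p"], abs=1e-12)
    with pytest.raises(ValidationError):
        rank_sum_test([], [1.0])


def test_kruskal_two_groups_equals_ranksum_squared(rng):
    x, y = rng.normal(size=30), rng.normal(size=30) + 0.3
    kw = kruskal_wallis([x, y])
    rs = rank_sum_test(x, y)
    # for 2 untied groups H = z^2, so the chi2(1) p equals the normal p
    # (up to the continuity correction in the normal approximation)
    assert kw["p"] == pytest.approx(rs["p"], abs=1e-2)


def test_kruskal_separated_groups():
    got = kruskal_wallis([[1, 2, 3, 4], [11, 12, 13, 14], [21, 22, 23, 24]])
    assert got["p"] < 0.01
    flat = kruskal_wallis([[5, 5], [5, 5]])
    assert flat == {"H": 0.0, "p": 1.0}


def test_kruskal_features_matches_scipy(rng):
    from scipy import stats as sps
    X = rng.normal(size=(24, 40))
    X[:, 0] = 1.0  # constant column
    labels = np.repeat([0, 1, 2], 8)
    H, p = kruskal_wallis_features(X, labels)
    assert H[0] == 0.0 and p[0] == 1.0
    for j in range(1, 20):
        ref = sps.kruskal(*(X[labels == g, j] for g in range(3)))
        assert H[j] == pytest.approx(ref.statistic, abs=1e-10)
        assert p[j] == pytest.approx(ref.pvalue, abs=1e-12)


def test_bh_fdr_step_up():
    got = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)
    # hand step-up on an unsorted vector
    got2 = bh_fdr([0.03, 0.005, 0.5])
    assert np.allclose(got2, [0.045, 0.015, 0.5])


def test_bh_fdr_properties(rng):
    p = rng.random(50)
    q = bh_fdr(p)
    assert (q >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    # a flat adjusted vector is a fixed point of the step-up
    flat = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(bh_fdr(flat), flat)
    with pytest.raises(ValidationError):
        bh_fdr([1.2])


# ---------------------------------------------------------------------
# LEfSe-style screen
# ---------------------------------------------------------------------

def _two_class_table(rng, n_per=15, n_taxa=10, boost_taxon=None, fold=1.0):
    a = np.full(n_taxa, 1.0)
    X = rng.dirichlet(a, size=2 * n_per)
    if boost_taxon is not None:
        X[n_per:, boost_taxon] *= fold
        X = X / X.sum(axis=1, keepdims=True)
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return make_table(X.T), labels


def test_lefse_flat_feature_absent(rng):
    t, labels = _two_class_table(rng)
    # make taxon 0 identical across all samples
    vals = t.values.copy()
    vals[0] = vals[0].mean()
    vals = vals / vals.sum(axis=0)
    t2 = make_table(vals)
    feats = lefse_screen(t2, labels, seed=0)
    assert all(f.taxon.name != "g00" for f in feats)


def test_lefse_strong_signal_retained(rng):
    t, labels = _two_class_table(rng, boost_taxon=3, fold=100.0)
    feats = lefse_screen(t, labels, seed=0)
    names = [f.taxon.name for f in feats]
    assert "g03" in names
    f = feats[names.index("g03")]
    assert f.lda_score > 2.0
    assert f.enriched_in == "B"
    assert f.q >= f.p


def test_lefse_reproducible_and_rankable(rng):
    t, labels = _two_class_table(rng, boost_taxon=2, fold=8.0)
    f1 = lefse_screen(t, labels, seed=7)
    f2 = lefse_screen(t, labels, seed=7)
    assert [(f.taxon, f.lda_score) for f in f1] == [(f.taxon, f.lda_score) for f in f2]
    # threshold 0, alpha 1: every feature returned, ranked by score
    allf = lefse_screen(t, labels, alpha=1.0, lda_threshold=-1.0, seed=7)
    assert len(allf) == t.n_taxa
    scores = [f.lda_score for f in allf]
    assert scores == sorted(scores, reverse=True)


def test_lefse_requires_two_classes(rng):
    t, labels = _two_class_table(rng)
    with pytest.raises(ValidationError):
        lefse_screen(t, np.array(["A"] * len(labels)))


# ---------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------

def test_permanova_hand_example():
    # 4 samples, 2 groups; independent arithmetic from the F definition
    D = np.array([
        [0.0, 0.1, 0.8, 0.9],
        [0.1, 0.0, 0.7, 0.6],
        [0.8, 0.7, 0.0, 0.2],
        [0.9, 0.6, 0.2, 0.0],
    ])
    dm = DistanceMatrix(["a", "b", "c", "d"], D, "bray_curtis")
    labels = np.array([0, 0, 1, 1])
    res = permanova(dm, labels, n_perm=99, seed=0)
    d2 = D ** 2
    ss_total = d2[np.triu_indices(4, 1)].sum() / 4
    ss_within = (d2[0, 1] + d2[2, 3]) / 2
    f_expect = (ss_total - ss_within) / 1 / (ss_within / 2)
    assert res.pseudo_F == pytest.approx(f_expect, abs=1e-12)
    assert res.R2 == pytest.approx((ss_total - ss_within) / ss_total, abs=1e-12)


def test_permanova_perfect_separation(rng):
    # two tight, well-separated clusters of 10; at n=20 the chance of a
    # permutation re-creating the split is negligible, so p hits its floor
    centers = np.array([[0.9, 0.05, 0.05], [0.05, 0.05, 0.9]])
    vals = np.repeat(centers, 10, axis=0)
    vals += rng.random(vals.shape) * 1e-3
    vals /= vals.sum(axis=1, keepdims=True)
    t = make_table(vals.T)
    dm = pairwise_distances(t, "bray_curtis")
    labels = np.repeat([0, 1], 10)
    res = permanova(dm, labels, n_perm=199, seed=0)
    assert res.p == pytest.approx(1 / 200)


def test_permanova_matches_skbio(rng):
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova as sk_permanova
    comps = random_compositions(rng, 14, 6)
    t = make_table(comps.T)
    dm = pairwise_distances(t, "bray_curtis")
    labels = np.repeat([0, 1], 7)
    ours = permanova(dm, labels, n_perm=99, seed=0)
    theirs = sk_permanova(SkDM(dm.values, ids=dm.sample_ids),
                          [str(l) for l in labels], permutations=99)
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_permanova_group_size_guard():
    dm = DistanceMatrix(["a", "b", "c"], np.array(
        [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]), "jsd")
    with pytest.raises(ValidationError):
        permanova(dm, np.array([0, 0, 1]))
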