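"""PAM clustering, validity indices, driver identification, BCA and
partition comparison."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from enterokit import (DistanceMatrix, assign_drivers, bca, calinski_harabasz,
                       compare_partitions, davies_bouldin, dunn_index, pam,
                       pcoa, pairwise_distances, select_K, silhouette_width,
                       Enterotyper)
from enterokit.io import ValidationError

from conftest import make_table, random_compositions


def _dm_from_points(points):
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    D = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    D = D / max(D.max(), 1.0)
    return DistanceMatrix([f"s{i}" for i in range(len(points))], D, "euclidean")


def _brute_force_pam_cost(D, K):
    n = D.shape[0]
    best = np.inf
    for meds in itertools.combinations(range(n), K):
        cost = D[:, meds].min(axis=1).sum()
        best = min(best, cost)
    return best


def test_pam_separates_clouds():
    dm = _dm_from_points([0.0, 0.1, 0.2, 10.0, 10.1])
    m = pam(dm, 2)
    labels = m.labels(dm.sample_ids)
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
    assert labels[0] != labels[3]
    # canonical labels: larger cluster is 1
    assert labels[0] == 1


def test_pam_matches_exhaustive_optimum(rng):
    for _ in range(60):
        n = int(rng.integers(4, 7))
        K = int(rng.integers(2, min(4, n)))
        pts = rng.normal(size=(n, 2))
        dm = _dm_from_points(pts)
        m = pam(dm, K)
        assert m.total_cost == pytest.approx(
            _brute_force_pam_cost(dm.values, K), abs=1e-9)


def test_pam_duplicated_dataset(rng):
    pts = rng.normal(size=(5, 2))
    dm1 = _dm_from_points(pts)
    dm2 = _dm_from_points(np.vstack([pts, pts]))
    m1, m2 = pam(dm1, 2), pam(dm2, 2)
    assert m2.total_cost == pytest.approx(2 * m1.total_cost, abs=1e-9)


def test_pam_parameter_errors():
    dm = _dm_from_points([0.0, 1.0, 2.0])
    with pytest.raises(ValueError):
        pam(dm, 1)
    with pytest.raises(ValueError):
        pam(dm, 3)


# ---------------------------------------------------------------------
# validity indices vs independent oracles
# ---------------------------------------------------------------------

def test_ch_matches_sklearn(rng):
    X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(5, 1, (15, 3))])
    labels = np.array([0] * 20 + [1] * 15)
    from enterokit.distance import PcoaEmbedding
    emb = PcoaEmbedding([f"s{i}" for i in range(35)], X,
                        np.ones(3), np.ones(3) / 3)
    ours = calinski_harabasz(emb, labels)
    assert ours == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-9)


def test_ch_perfect_separation_sentinel():
    X = np.array([[0.0], [0.0], [10.0], [10.0]])
    from enterokit.distance import PcoaEmbedding
    emb = PcoaEmbedding(["a", "b", "c", "d"], X, np.ones(1), np.ones(1))
    assert calinski_harabasz(emb, np.array([1, 1, 2, 2])) == np.inf


def test_ch_separation_beats_random_relabeling(rng):
    X = np.vstack([rng.normal(0, 0.5, (15, 2)), rng.normal(8, 0.5, (15, 2))])
    from enterokit.distance import PcoaEmbedding
    emb = PcoaEmbedding([f"s{i}" for i in range(30)], X, np.ones(2), np.ones(2))
    good = calinski_harabasz(emb, np.array([1] * 15 + [2] * 15))
    bad = calinski_harabasz(emb, rng.permutation([1] * 15 + [2] * 15))
    assert good > 10 * bad


def test_silhouette_hand_computation():
    # 4 points on a line: 0, 1, 10, 11; clusters {0,1}, {10,11}
    dm = _dm_from_points([0.0, 1.0, 10.0, 11.0])
    D = dm.values
    mean, s = silhouette_width(dm, np.array([1, 1, 2, 2]))
    for i, (own, other) in enumerate([(1, [2, 3]), (0, [2, 3]),
                                      (3, [0, 1]), (2, [0, 1])]):
        a = D[i, own]
        b = D[i, other].mean()
        assert s[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)
    assert mean == pytest.approx(s.mean(), abs=1e-12)


def test_silhouette_duplicated_points_is_one():
    dm = _dm_from_points([0.0, 0.0, 5.0, 5.0])
    mean, _ = silhouette_width(dm, np.array([1, 1, 2, 2]))
    assert mean == pytest.approx(1.0)


def test_silhouette_matches_sklearn(rng):
    pts = rng.normal(size=(20, 2))
    dm = _dm_from_points(pts)
    labels = rng.integers(1, 4, 20)
    while len(np.unique(labels)) < 3 or (np.bincount(labels)[1:] < 2).any():
        labels = rng.integers(1, 4, 20)
    ours, _ = silhouette_width(dm, labels)
    theirs = silhouette_score(dm.values, labels, metric="precomputed")
    assert ours == pytest.approx(theirs, abs=1e-9)


def test_silhouette_requires_two_clusters():
    dm = _dm_from_points([0.0, 1.0, 2.0])
    with pytest.raises(ValidationError):
        silhouette_width(dm, np.array([1, 1, 1]))


def test_dbi_tight_clusters_zero():
    dm = _dm_from_points([0.0, 0.0, 7.0, 7.0])
    assert davies_bouldin(dm, np.array([1, 1, 2, 2]), ["s0", "s2"]) == 0.0


def test_dbi_brute_force_oracle(rng):
    for _ in range(30):
        pts = rng.normal(size=(12, 2))
        dm = _dm_from_points(pts)
        labels = np.array([1] * 4 + [2] * 4 + [3] * 4)
        meds = ["s0", "s4", "s8"]
        ours = davies_bouldin(dm, labels, meds)
        D = dm.values
        S = [D[m, labels == k].mean() for k, m in [(1, 0), (2, 4), (3, 8)]]
        mi = [0, 4, 8]
        expect = np.mean([
            max((S[a] + S[b]) / D[mi[a], mi[b]] for b in range(3) if b != a)
            for a in range(3)
        ])
        assert ours == pytest.approx(expect, abs=1e-9)


def test_dunn_direct_construction():
    # two clusters: diameters 1 and 1 (scaled), min separation 10
    pts = [0.0, 1.0, 11.0, 12.0]
    dm = _dm_from_points(pts)
    got = dunn_index(dm, np.array([1, 1, 2, 2]))
    assert got == pytest.approx(10.0, abs=1e-9)


def test_dunn_nested_below_one_and_relabel_invariant(rng):
    pts = rng.normal(size=(10, 2))
    dm = _dm_from_points(pts)
    labels = rng.integers(1, 3, 10)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(1, 3, 10)
    d1 = dunn_index(dm, labels)
    d2 = dunn_index(dm, 3 - labels)  # swap cluster names
    assert d1 == pytest.approx(d2, abs=1e-12)


# ---------------------------------------------------------------------
# select_K, drivers
# ---------------------------------------------------------------------

def test_select_K_duplicated_compositions():
    comps = np.array([[0.9, 0.1, 0.0], [0.05, 0.05, 0.9]])
    vals = np.repeat(comps, 5, axis=0).T
    t = make_table(vals)
    dm = pairwise_distances(t, "jsd")
    curve = select_K(dm, range(2, 5))
    assert curve.chosen_K == 2
    assert curve.silhouette[0] == pytest.approx(1.0)


def test_select_K_three_component_mixture(rng):
    alphas = [np.array([20, 1, 1, 1, 1.0]), np.array([1, 20, 1, 1, 1.0]),
              np.array([1, 1, 20, 1, 1.0])]
    comps = np.vstack([rng.dirichlet(a, size=15) for a in alphas])
    t = make_table(comps.T)
    dm = pairwise_distances(t, "jsd")
    curve = select_K(dm, range(2, 6))
    assert curve.chosen_K == 3
    truth = np.repeat([1, 2, 3], 15)
    ari = compare_partitions(curve.models[3].labels(t.samples), truth)["ari"]
    assert ari >= 0.9


def test_select_K_order_invariant(rng):
    comps = random_compositions(rng, 12, 5)
    t = make_table(comps.T)
    perm = rng.permutation(12)
    t2 = make_table(comps[perm].T, samples=[t.samples[i] for i in perm])
    c1 = select_K(pairwise_distances(t, "jsd"), range(2, 5))
    c2 = select_K(pairwise_distances(t2, "jsd"), range(2, 5))
    assert c1.chosen_K == c2.chosen_K


def test_assign_drivers_dominant_genus():
    vals = np.array([
        [0.9, 0.92, 0.05, 0.03],
        [0.05, 0.05, 0.9, 0.9],
        [0.05, 0.03, 0.05, 0.07],
    ])
    t = make_table(vals, taxa=["Prevotella", "Bacteroides", "Other"])
    dm = pairwise_distances(t, "jsd")
    m = assign_drivers(pam(dm, 2), t)
    drivers = {m.driver_taxon[k].name for k in (1, 2)}
    assert drivers == {"Prevotella", "Bacteroides"}
    # per-cluster profiles are compositions
    assert np.allclose(m.cluster_profiles.sum(axis=1), 1.0, atol=1e-9)


def test_bca_identical_groups_ratio_zero(rng):
    comp = rng.dirichlet(np.ones(5))
    vals = np.tile(comp[:, None], (1, 8))
    t = make_table(vals)
    res = bca(t, np.array([1, 1, 1, 1, 2, 2, 2, 2]))
    assert res.between_inertia_ratio == pytest.approx(0.0, abs=1e-9)


def test_bca_disjoint_groups(rng):
    g1 = rng.dirichlet([50, 1, 1, 1], size=10)
    g2 = rng.dirichlet([1, 1, 1, 50], size=10)
    t = make_table(np.vstack([g1, g2]).T)
    labels = np.array([1] * 10 + [2] * 10)
    res = bca(t, labels)
    assert res.between_inertia_ratio > 0.8
    # first-axis loadings dominated by the two discriminating taxa
    lead = np.abs(res.axes[:, 0])
    assert set(np.argsort(lead)[-2:]) == {0, 3}
    # group mean score equals projected centroid
    for g in (1, 2):
        assert np.allclose(res.sample_scores[labels == g].mean(axis=0),
                           res.group_centroids[g], atol=1e-9)
    # axes orthonormal
    assert np.allclose(res.axes.T @ res.axes, np.eye(res.axes.shape[1]), atol=1e-9)


def _brute_force_ari(a, b):
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, 1)
    n11 = (same_a[iu] & same_b[iu]).sum()
    n00 = (~same_a[iu] & ~same_b[iu]).sum()
    n10 = (same_a[iu] & ~same_b[iu]).sum()
    n01 = (~same_a[iu] & same_b[iu]).sum()
    total = n11 + n00 + n10 + n01
    expected = (n11 + n10) * (n11 + n01) / total
    maxi = 0.5 * ((n11 + n10) + (n11 + n01))
    if maxi == expected:
        return 1.0
    return (n11 - expected) / (maxi - expected)


def test_compare_partitions_examples(rng):
    a = np.array([1, 1, 2, 2, 3, 3])
    assert compare_partitions(a, a)["ari"] == pytest.approx(1.0)
    singletons = np.arange(6)
    lumped = np.ones(6)
    assert compare_partitions(singletons, lumped)["ari"] == pytest.approx(0.0)
    for _ in range(20):
        x = rng.integers(1, 4, 12)
        y = rng.integers(1, 4, 12)
        got = compare_partitions(x, y)
        assert got["ari"] == pytest.approx(_brute_force_ari(x, y), abs=1e-12)
        assert got["cross_tab"].to_numpy().sum() == 12


def test_compare_partitions_sample_mismatch():
    with pytest.raises(ValidationError):
        compare_partitions({"a": 1, "b": 2}, {"a": 1, "c": 2})


def test_enterotyper_results_summary(rng):
    g1 = rng.dirichlet([30, 1, 1, 1, 1], size=12)
    g2 = rng.dirichlet([1, 30, 1, 1, 1], size=8)
    t = make_table(np.vstack([g1, g2]).T,
                   taxa=["Prevotella", "Bacteroides", "a", "b", "c"])
    res = Enterotyper(t, metric="jsd").fit(K_range=range(2, 4))
    assert res.K == 2
    s = res.summary()
    assert set(s["driver"]) == {"Prevotella", "Bacteroides"}
    assert s.loc["E1", "n"] == 12  # labels ordered by decreasing size
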