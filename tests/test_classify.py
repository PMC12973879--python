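"""Feature panels and random-forest evaluation."""

import numpy as np
import pytest
from scipy.stats import rankdata

from enterokit import (build_panel, compare_models, pairwise_distances, pam,
                       train_evaluate, union_panels, FeaturePanel, TaxonId)
from enterokit.io import ValidationError

from conftest import make_table

SMALL_GRID = {"n_estimators": [60], "max_depth": [None]}


def _clustered_table(rng, n_per=12, n_taxa=8):
    g1 = rng.dirichlet(np.r_[30, np.ones(n_taxa - 1)], size=n_per)
    g2 = rng.dirichlet(np.r_[np.ones(n_taxa - 1), 30], size=n_per)
    return make_table(np.vstack([g1, g2]).T)


def test_build_panel_recovery_and_order(rng):
    t = _clustered_table(rng)
    m = pam(pairwise_distances(t, "jsd"), 2)
    panel = build_panel(m, t, cluster=1, top_n=3)
    labels = m.labels(t.samples)
    mean = t.data.loc[:, labels == 1].mean(axis=1).sort_values(ascending=False)
    assert [x.name for x in panel.taxa] == list(mean.index.get_level_values("name")[:3])
    # order invariant to sample permutation
    perm = rng.permutation(t.n_samples)
    t2 = make_table(t.values[:, perm], samples=[t.samples[i] for i in perm])
    panel2 = build_panel(m, t2, cluster=1, top_n=3)
    assert panel.taxa == panel2.taxa


def test_build_panel_short_flag(rng):
    vals = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
    t = make_table(vals)
    m = pam(pairwise_distances(t, "jsd"), 2)
    panel = build_panel(m, t, cluster=1, top_n=10)
    assert panel.short and len(panel.taxa) == 1


def test_union_panels_semantics():
    a = FeaturePanel("a", [TaxonId("bacteria", "genus", x) for x in "pqr"], "src-a")
    b = FeaturePanel("b", [TaxonId("fungi", "genus", x) for x in "xyz"], "src-b")
    u = union_panels([a, b])
    assert len(u.taxa) == 6
    assert union_panels([a, a]).taxa == a.taxa  # idempotent
    c = FeaturePanel("c", [a.taxa[1], TaxonId("fungi", "genus", "w")], "src-c")
    uc = union_panels([a, c])
    assert [t.name for t in uc.taxa] == ["p", "q", "r", "w"]  # first occurrence wins


def test_separable_panel_perfect_auc(rng):
    vals = np.zeros((4, 40))
    vals[0, :20] = 0.9; vals[1, :20] = 0.1
    vals[2, 20:] = 0.9; vals[3, 20:] = 0.1
    vals += rng.random((4, 40)) * 1e-3
    vals /= vals.sum(axis=0)
    t = make_table(vals)
    labels = np.array(["neg"] * 20 + ["pos"] * 20)
    panel = FeaturePanel("sep", [TaxonId("bacteria", "genus", f"g{i:02d}")
                                 for i in range(4)], "toy")
    rep = train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=0, n_boot=30)
    assert rep.auc == 1.0
    assert rep.f1 == 1.0


def test_metrics_consistent_with_confusion(rng):
    X = rng.dirichlet(np.ones(6), size=60)
    X[30:, 0] *= 3
    X = X / X.sum(axis=1, keepdims=True)
    t = make_table(X.T)
    labels = np.array(["a"] * 30 + ["b"] * 30)
    panel = FeaturePanel("p", [TaxonId("bacteria", "genus", f"g{i:02d}")
                               for i in range(6)], "toy")
    rep = train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=1, n_boot=20)
    tn, fp, fn, tp = rep.confusion.ravel()
    assert rep.sensitivity == pytest.approx(tp / (tp + fn))
    assert rep.specificity == pytest.approx(tn / (tn + fp))
    assert rep.accuracy == pytest.approx((tp + tn) / rep.confusion.sum())
    assert rep.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
    assert rep.confusion.sum() == len(rep.test_sample_ids)
    assert sum(rep.importances.values()) == pytest.approx(1.0, abs=1e-9)


def test_auc_equals_rank_statistic(rng):
    X = rng.dirichlet(np.ones(5), size=50)
    X[25:, 1] *= 2
    X = X / X.sum(axis=1, keepdims=True)
    t = make_table(X.T)
    labels = np.array(["a"] * 25 + ["b"] * 25)
    panel = FeaturePanel("p", [TaxonId("bacteria", "genus", f"g{i:02d}")
                               for i in range(5)], "toy")
    rep = train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=3, n_boot=10)
    y, s = rep.y_true, rep.y_score
    r = rankdata(s)
    n1, n0 = y.sum(), (1 - y).sum()
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2
    assert rep.auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_permuted_labels_near_chance(rng):
    means = []
    for seed in range(6):
        r = np.random.default_rng(seed)
        X = r.dirichlet(np.ones(8), size=80)
        t = make_table(X.T)
        labels = r.permutation(np.array(["a"] * 40 + ["b"] * 40))
        panel = FeaturePanel("p", [TaxonId("bacteria", "genus", f"g{i:02d}")
                                   for i in range(8)], "toy")
        rep = train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=seed,
                             n_boot=50)
        means.append(rep.bootstrap_auc.mean())
    assert 0.35 <= np.mean(means) <= 0.65


def test_reproducible_with_fixed_seeds(rng):
    X = rng.dirichlet(np.ones(6), size=40)
    t = make_table(X.T)
    labels = np.array(["a"] * 20 + ["b"] * 20)
    panel = FeaturePanel("p", [TaxonId("bacteria", "genus", f"g{i:02d}")
                               for i in range(6)], "toy")
    r1 = train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=11, n_boot=25)
    r2 = train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=11, n_boot=25)
    assert r1.auc == r2.auc
    assert np.array_equal(r1.bootstrap_auc, r2.bootstrap_auc)
    assert r1.importances == r2.importances


def test_compare_models_self_and_ranking(rng):
    X = rng.dirichlet(np.ones(6), size=60)
    X[30:, 0] *= 4
    X = X / X.sum(axis=1, keepdims=True)
    t = make_table(X.T)
    labels = np.array(["a"] * 30 + ["b"] * 30)
    informative = FeaturePanel("inf", [TaxonId("bacteria", "genus", "g00")], "t")
    noise = FeaturePanel("noise", [TaxonId("bacteria", "genus", "g05")], "t")
    r_inf = train_evaluate(t, informative, labels, grid=SMALL_GRID, seed=2, n_boot=10)
    r_noise = train_evaluate(t, noise, labels, grid=SMALL_GRID, seed=2, n_boot=10)
    out = compare_models({"inf": r_inf, "self": r_inf, "noise": r_noise},
                         n_boot=300, seed=0)
    row = out[(out.model_a == "inf") & (out.model_b == "self")].iloc[0]
    assert row.auc_diff == 0.0
    assert row.ci_low <= 0 <= row.ci_high
    assert out.attrs["ranking"][0] in ("inf", "self")


def test_missing_panel_feature_errors(rng):
    X = rng.dirichlet(np.ones(4), size=20)
    t = make_table(X.T)
    labels = np.array(["a"] * 10 + ["b"] * 10)
    panel = FeaturePanel("bad", [TaxonId("bacteria", "genus", "absent")], "t")
    with pytest.raises(ValidationError, match="absent"):
        train_evaluate(t, panel, labels, grid=SMALL_GRID, seed=0)
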