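"""Group-difference testing: rank tests, BH-FDR, a LEfSe-style LDA
effect-size screen, and PERMANOVA on distance matrices.

The rank tests delegate to scipy; PERMANOVA and the LEfSe-style screen
are implemented here (the screen's effect size is a documented
pooled-covariance-discriminant approximation of the reference LEfSe
procedure: Kruskal-Wallis gate, per-sample rescaling to 1e6, bootstrap
one-axis LDA, log10 effect score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .distance import DistanceMatrix
from .io import AbundanceTable, TaxonId, ValidationError

__all__ = [
    "DifferentialFeature",
    "PermanovaResult",
    "rank_sum_test",
    "signed_rank_test",
    "kruskal_wallis",
    "kruskal_wallis_features",
    "bh_fdr",
    "lefse_screen",
    "permanova",
]


@dataclass
class DifferentialFeature:
    taxon: TaxonId
    statistic: float
    p: float
    q: float
    lda_score: float
    enriched_in: str


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def rank_sum_test(x, y) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small untied samples; normal approximation with
    tie correction otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty group")
    small = len(x) <= 20 and len(y) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def signed_rank_test(x, y) -> dict:
    """Two-sided Wilcoxon signed-rank test for paired observations."""
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return {"W": float(res.statistic), "p": float(res.pvalue)}


def kruskal_wallis(groups) -> dict:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0}
    res = sps.kruskal(*groups)
    return {"H": float(res.statistic), "p": float(res.pvalue)}


def kruskal_wallis_features(X: np.ndarray, labels: np.ndarray):
    """Vectorized Kruskal-Wallis across the columns of a samples x
    features matrix. Returns (H, p) arrays; constant columns get H=0,
    p=1."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n, m = X.shape
    uniq = np.unique(labels)
    k = len(uniq)
    R = sps.rankdata(X, axis=0)
    H = np.zeros(m)
    for u in uniq:
        mask = labels == u
        ng = mask.sum()
        H += R[mask].sum(axis=0) ** 2 / ng
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    # tie correction per column
    Xs = np.sort(X, axis=0)
    ties = np.zeros(m)
    for j in range(m):
        _, counts = np.unique(Xs[:, j], return_counts=True)
        ties[j] = (counts ** 3 - counts).sum()
    corr = 1.0 - ties / (n ** 3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(corr > 0, H / corr, 0.0)
    H = np.maximum(H, 0.0)
    p = np.where(H > 0, sps.chi2.sf(H, k - 1), 1.0)
    return H, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _ridge_lda_direction(X0: np.ndarray, X1: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Pooled-covariance linear-discriminant direction with ridge term."""
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S = (np.cov(X0, rowvar=False, bias=False) * (n0 - 1)
         + np.cov(X1, rowvar=False, bias=False) * (n1 - 1)) / max(n0 + n1 - 2, 1)
    S = np.atleast_2d(S)
    S = S + ridge * np.trace(S) / S.shape[0] * np.eye(S.shape[0]) + ridge * np.eye(S.shape[0])
    return np.linalg.solve(S, mu1 - mu0)


def lefse_screen(table: AbundanceTable, labels, alpha: float = 0.05,
                 lda_threshold: float = 2.0, n_boot: int = 30, seed: int = 0,
                 p_adjust: str = "fdr_bh", rescale: float = 1e6,
                 subsample_frac: float = 2 / 3) -> list[DifferentialFeature]:
    """LEfSe-style differential-feature screen for a two-class design.

    1. Per-feature Kruskal-Wallis gate at ``alpha`` (BH-adjusted unless
       ``p_adjust='none'``).
    2. Abundances rescaled to a per-sample sum of ``rescale``.
    3. ``n_boot`` bootstrap rounds, each subsampling ``subsample_frac``
       of every class and fitting a one-axis ridge-regularized linear
       discriminant on the retained features; the per-feature round
       effect is ``|0.5 * (w_f * delta_axis + delta_f)|``.
    4. ``lda_score = log10(1 + mean effect)``; retained if above
       ``lda_threshold``.
    """
    if isinstance(labels, dict):
        y = np.array([labels[s] for s in table.samples])
    else:
        y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("lefse_screen requires exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 samples")
    X = table.matrix()  # samples x taxa
    H, p = kruskal_wallis_features(X, y)
    if p_adjust == "fdr_bh":
        q = bh_fdr(p)
    elif p_adjust == "none":
        q = p.copy()
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    keep = np.where(q < alpha)[0]
    if keep.size == 0:
        return []

    Xs = X * rescale
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.where(y == classes[0])[0], np.where(y == classes[1])[0]
    n0 = max(int(np.ceil(subsample_frac * len(idx0))), 2)
    n1 = max(int(np.ceil(subsample_frac * len(idx1))), 2)
    effects = np.zeros((n_boot, keep.size))
    for b in range(n_boot):
        s0 = rng.choice(idx0, size=n0, replace=False)
        s1 = rng.choice(idx1, size=n1, replace=False)
        X0, X1 = Xs[np.ix_(s0, keep)], Xs[np.ix_(s1, keep)]
        w = _ridge_lda_direction(X0, X1)
        nw = np.linalg.norm(w)
        if nw > 0:
            w = w / nw
        delta_axis = float((X1 @ w).mean() - (X0 @ w).mean())
        delta_f = X1.mean(axis=0) - X0.mean(axis=0)
        effects[b] = np.abs(0.5 * (w * delta_axis + delta_f))
    mean_eff = effects.mean(axis=0)
    lda_scores = np.log10(1.0 + mean_eff)

    taxa = table.taxa
    out: list[DifferentialFeature] = []
    overall1 = X[idx1].mean(axis=0)
    overall0 = X[idx0].mean(axis=0)
    for pos, f in enumerate(keep):
        if lda_scores[pos] > lda_threshold:
            enriched = classes[1] if overall1[f] > overall0[f] else classes[0]
            out.append(DifferentialFeature(
                taxon=taxa[f], statistic=float(H[f]), p=float(p[f]),
                q=float(q[f]), lda_score=float(lda_scores[pos]),
                enriched_in=str(enriched),
            ))
    out.sort(key=lambda d: -d.lda_score)
    return out


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
              ) -> PermanovaResult:
    """One-way PERMANOVA with the adonis squared-dissimilarity convention.

    p includes the observed statistic in the null set, so the smallest
    attainable p is 1/(1+n_perm).
    """
    if isinstance(labels, dict):
        y = np.array([labels[s] for s in dm.sample_ids])
    else:
        y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    D2 = dm.values ** 2
    n, a = len(y), len(uniq)
    ss_total = D2.sum() / (2 * n)
    groups = [np.where(y == u)[0] for u in uniq]

    def ss_within(perm: np.ndarray) -> float:
        s = 0.0
        for g in groups:
            ix = perm[g]
            s += D2[np.ix_(ix, ix)].sum() / (2 * len(ix))
        return s

    ident = np.arange(n)
    ssw = ss_within(ident)
    ssb = ss_total - ssw
    f_obs = (ssb / (a - 1)) / (ssw / (n - a))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssw_p = ss_within(perm)
        f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(ssb / ss_total), float(p), n_perm)
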