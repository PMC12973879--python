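"""Enterotype calling: PAM clustering over a distance matrix, cluster
validity indices, K selection, driver-genus identification and
between-class ordination.

The fitted-model surface is :class:`Enterotyper` (constructed from an
abundance table or a precomputed distance matrix) whose :meth:`fit`
returns an :class:`EnterotypeResults` carrying the partition, validity
curves, driver taxa and a ``summary()`` table.

PAM here is the classical BUILD + SWAP k-medoids: greedy seeding, then
best-improvement swaps to a local optimum of the total distance of every
sample to its medoid. Tie-breaking is deterministic (lowest sample
index), so a fit is reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .distance import DistanceMatrix, PcoaEmbedding, pairwise_distances, pcoa
from .io import AbundanceTable, TaxonId, ValidationError

__all__ = [
    "EnterotypeModel",
    "ValidityCurve",
    "BcaResult",
    "pam",
    "calinski_harabasz",
    "silhouette_width",
    "davies_bouldin",
    "dunn_index",
    "select_K",
    "assign_drivers",
    "bca",
    "compare_partitions",
    "Enterotyper",
    "EnterotypeResults",
]

_EPS = 1e-12


@dataclass
class EnterotypeModel:
    """A fitted PAM partition. Labels are 1..K, ordered by decreasing
    cluster size (ties broken by lowest medoid index)."""

    metric: str
    K: int
    medoid_ids: list[str]                 # medoid of cluster k at position k-1
    assignment: dict[str, int]            # sample_id -> 1..K
    total_cost: float
    driver_taxon: dict[int, TaxonId] = field(default_factory=dict)
    cluster_profiles: pd.DataFrame | None = None   # label x taxa mean abundance
    driver_ties: dict[int, list[str]] = field(default_factory=dict)

    def labels(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[s] for s in sample_ids])


@dataclass
class ValidityCurve:
    metric: str
    K_range: list[int]
    ch: list[float]
    silhouette: list[float]
    dbi: list[float]
    dunn: list[float]
    chosen_K: int
    models: dict[int, EnterotypeModel] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.K_range, "ch": self.ch, "silhouette": self.silhouette,
             "dbi": self.dbi, "dunn": self.dunn}
        ).set_index("K")


@dataclass
class BcaResult:
    axes: np.ndarray              # taxa x m orthonormal loadings
    sample_scores: np.ndarray     # n x m
    group_centroids: dict[int, np.ndarray]
    between_inertia_ratio: float
    taxa: list[TaxonId] | None = None


# ----------------------------------------------------------------------
# PAM
# ----------------------------------------------------------------------

def pam(dm: DistanceMatrix, K: int, seed: int = 0) -> EnterotypeModel:
    """Partitioning Around Medoids over a precomputed distance matrix.

    BUILD greedily seeds medoids to minimize total cost; SWAP applies the
    best strictly-improving medoid/non-medoid exchange until none exists.
    Deterministic: ties resolve to the lowest sample index (``seed`` is
    accepted for interface symmetry; the algorithm itself is
    deterministic).
    """
    D = dm.values
    n = D.shape[0]
    if not (2 <= K < n):
        raise ValueError(f"K must satisfy 2 <= K < n_samples, got K={K}, n={n}")

    import math
    if math.comb(n, K) * n <= 200_000:
        # tiny instance: the medoid problem is solved exactly by
        # enumeration (ties -> lexicographically first subset)
        import itertools
        best_cost, best_meds = np.inf, None
        for meds in itertools.combinations(range(n), K):
            cost = D[:, meds].min(axis=1).sum()
            if cost < best_cost - _EPS:
                best_cost, best_meds = cost, meds
        return _finalize(dm, D, list(best_meds), K)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < K:
        cand = np.setdiff1d(np.arange(n), medoids)
        # gain of adding c: sum over j of max(dnear_j - D[j,c], 0)
        gains = np.maximum(dnear[:, None] - D[:, cand], 0.0).sum(axis=0)
        best = cand[int(np.argmax(gains))]  # argmax takes first (lowest index) on ties
        medoids.append(int(best))
        dnear = np.minimum(dnear, D[:, best])

    medoids = sorted(medoids)

    # SWAP (best improvement, deterministic tie-break)
    while True:
        med = np.array(medoids)
        Dm = D[:, med]                               # n x K
        order = np.argsort(Dm, axis=1, kind="stable")
        d1 = Dm[np.arange(n), order[:, 0]]
        d2 = Dm[np.arange(n), order[:, 1]]
        nearest = med[order[:, 0]]
        cand = np.setdiff1d(np.arange(n), med)
        best_delta, best_swap = -_EPS, None
        for mi in medoids:
            mask = nearest == mi
            Dc = D[:, cand]
            a = np.minimum(Dc[mask], d2[mask, None]) - d1[mask, None]
            b = np.minimum(Dc[~mask] - d1[~mask, None], 0.0)
            delta = a.sum(axis=0) + b.sum(axis=0)
            j = int(np.argmin(delta))
            if delta[j] < best_delta - _EPS or (
                best_swap is not None
                and abs(delta[j] - best_delta) <= _EPS
                and (mi, int(cand[j])) < best_swap
            ):
                best_delta, best_swap = float(delta[j]), (mi, int(cand[j]))
        if best_swap is None or best_delta >= -_EPS:
            break
        out_m, in_m = best_swap
        medoids = sorted(set(medoids) - {out_m} | {in_m})

    return _finalize(dm, D, medoids, K)


def _finalize(dm: DistanceMatrix, D: np.ndarray, medoids: list[int],
              K: int) -> EnterotypeModel:
    """Assign samples to nearest medoids (ties to the lowest medoid index)
    and canonicalize labels by decreasing cluster size."""
    n = D.shape[0]
    med = np.array(sorted(medoids))
    Dm = D[:, med]
    nearest_pos = np.argmin(Dm, axis=1)   # first minimum -> lowest medoid index
    total_cost = float(Dm[np.arange(n), nearest_pos].sum())
    sizes = np.bincount(nearest_pos, minlength=K)
    order = sorted(range(K), key=lambda k: (-sizes[k], med[k]))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[p] for p in nearest_pos])
    medoid_ids = [dm.sample_ids[med[old]] for old in order]
    assignment = {s: int(l) for s, l in zip(dm.sample_ids, labels)}
    return EnterotypeModel(dm.metric, K, medoid_ids, assignment, total_cost)


# ----------------------------------------------------------------------
# validity indices
# ----------------------------------------------------------------------

def _label_array(sample_ids, assignment) -> np.ndarray:
    if isinstance(assignment, dict):
        return np.array([assignment[s] for s in sample_ids])
    return np.asarray(assignment)


def calinski_harabasz(embedding: PcoaEmbedding, assignment) -> float:
    """Variance-ratio criterion computed in PCoA space.

    CH = [B/(K-1)] / [W/(n-K)] with B, W the between- and within-cluster
    sums of squared Euclidean distances to centroids. Perfect separation
    (W = 0) returns +inf.
    """
    X = embedding.coordinates
    labels = _label_array(embedding.sample_ids, assignment)
    uniq = np.unique(labels)
    K, n = len(uniq), len(labels)
    if K < 2:
        raise ValidationError("calinski_harabasz requires K >= 2")
    grand = X.mean(axis=0)
    B = W = 0.0
    for u in uniq:
        sub = X[labels == u]
        c = sub.mean(axis=0)
        B += len(sub) * float(((c - grand) ** 2).sum())
        W += float(((sub - c) ** 2).sum())
    if W <= _EPS:
        return float("inf")
    return (B / (K - 1)) / (W / (n - K))


def silhouette_width(dm: DistanceMatrix, assignment):
    """Mean silhouette from the distance matrix; singletons score 0.

    Returns ``(mean, per_sample)``.
    """
    D = dm.values
    labels = _label_array(dm.sample_ids, assignment)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette requires K >= 2")
    n = len(labels)
    s = np.zeros(n)
    masks = {u: labels == u for u in uniq}
    for i in range(n):
        own = masks[labels[i]]
        size = own.sum()
        if size == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (size - 1)
        b = min(D[i, masks[u]].mean() for u in uniq if u != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom <= _EPS else (b - a) / denom
    return float(s.mean()), s


def davies_bouldin(dm: DistanceMatrix, assignment, medoids: list[str]) -> float:
    """Medoid-based Davies-Bouldin index (lower is better).

    Scatter of cluster k is the mean distance of its members to its
    medoid; similarity of clusters k, j is (S_k + S_j) / d(medoid_k,
    medoid_j).
    """
    D = dm.values
    labels = _label_array(dm.sample_ids, assignment)
    idx = {s: i for i, s in enumerate(dm.sample_ids)}
    med_idx = [idx[m] for m in medoids]
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValidationError("davies_bouldin requires K >= 2")
    if len(med_idx) != len(uniq):
        raise ValidationError("one medoid per cluster required")
    S = []
    for u, m in zip(uniq, med_idx):
        members = labels == u
        S.append(float(D[m, members].mean()))
    total = 0.0
    for a, (ua, ma) in enumerate(zip(uniq, med_idx)):
        worst = 0.0
        for b, (ub, mb) in enumerate(zip(uniq, med_idx)):
            if a == b:
                continue
            sep = D[ma, mb]
            if sep <= _EPS:
                raise ValidationError(
                    f"coincident medoids {medoids[a]!r}, {medoids[b]!r}"
                )
            worst = max(worst, (S[a] + S[b]) / sep)
        total += worst
    return total / len(uniq)


def dunn_index(dm: DistanceMatrix, assignment) -> float:
    """Dunn index: min single-linkage separation / max complete diameter."""
    D = dm.values
    labels = _label_array(dm.sample_ids, assignment)
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValidationError("dunn_index requires K >= 2")
    masks = [labels == u for u in uniq]
    min_sep = min(
        D[np.ix_(masks[a], masks[b])].min()
        for a in range(len(uniq)) for b in range(a + 1, len(uniq))
    )
    max_diam = max(
        D[np.ix_(m, m)].max() if m.sum() > 1 else 0.0 for m in masks
    )
    if max_diam <= _EPS:
        return float("inf")
    return float(min_sep / max_diam)


def select_K(dm: DistanceMatrix, K_range=range(2, 9), seed: int = 0,
             embedding: PcoaEmbedding | None = None) -> ValidityCurve:
    """Run PAM across ``K_range`` and score each partition with four
    validity indices. ``chosen_K`` maximizes CH, with mean silhouette as
    tie-breaker (then the smaller K)."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K_range")
    if embedding is None:
        embedding = pcoa(dm)
    ch, sil, dbi, dun, models = [], [], [], [], {}
    for K in K_range:
        model = pam(dm, K, seed=seed)
        models[K] = model
        ch.append(calinski_harabasz(embedding, model.assignment))
        sil.append(silhouette_width(dm, model.assignment)[0])
        try:
            dbi.append(davies_bouldin(dm, model.assignment, model.medoid_ids))
        except ValidationError:
            dbi.append(float("nan"))
        dun.append(dunn_index(dm, model.assignment))
    best = max(
        range(len(K_range)),
        key=lambda i: (ch[i], sil[i], -K_range[i]),
    )
    return ValidityCurve(dm.metric, K_range, ch, sil, dbi, dun, K_range[best], models)


# ----------------------------------------------------------------------
# drivers, BCA, partition comparison
# ----------------------------------------------------------------------

def assign_drivers(model: EnterotypeModel, table: AbundanceTable) -> EnterotypeModel:
    """Name each cluster by its driver: the taxon with the highest mean
    relative abundance among member samples. Ties resolve lexicographically
    by taxon name and are recorded on the model."""
    missing = set(table.samples) - set(model.assignment)
    if missing:
        raise ValidationError(f"assignment does not cover samples {sorted(missing)}")
    labels = model.labels(table.samples)
    profiles = {}
    drivers: dict[int, TaxonId] = {}
    ties: dict[int, list[str]] = {}
    taxa = table.taxa
    for k in range(1, model.K + 1):
        members = labels == k
        mean = table.data.loc[:, members].mean(axis=1)
        profiles[k] = mean
        top = mean.max()
        tied = [TaxonId(*t) for t in mean.index[np.isclose(mean, top, rtol=0, atol=1e-15)]]
        tied.sort(key=lambda t: t.name)
        drivers[k] = tied[0]
        if len(tied) > 1:
            ties[k] = [t.name for t in tied]
    model.driver_taxon = drivers
    model.driver_ties = ties
    prof = pd.DataFrame(profiles).T
    prof.index.name = "cluster"
    model.cluster_profiles = prof
    return model


def bca(table: AbundanceTable, assignment, n_axes: int | None = None) -> BcaResult:
    """Between-class analysis: PCA of size-weighted group centroids of the
    column-centred sample x taxa matrix, with all samples projected onto
    the centroid axes."""
    X = table.matrix()  # n x t
    labels = _label_array(table.samples, assignment)
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValidationError("bca requires at least 2 groups")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    cents = np.array([Xc[labels == u].mean(axis=0) for u in uniq])
    w = np.array([(labels == u).sum() / n for u in uniq])
    # weighted PCA of the centroid matrix
    Cw = cents * np.sqrt(w)[:, None]
    _, svals, Vt = np.linalg.svd(Cw, full_matrices=False)
    keep = svals > 1e-12
    axes = Vt[keep].T                       # taxa x m, orthonormal
    if n_axes is not None:
        axes = axes[:, :n_axes]
    scores = Xc @ axes
    centroids = {u: cents[i] @ axes for i, u in enumerate(uniq)}
    between = float((w[:, None] * cents ** 2).sum()) * n
    total = float((Xc ** 2).sum())
    ratio = 0.0 if total <= _EPS else min(between / total, 1.0)
    return BcaResult(axes, scores, centroids, ratio, table.taxa)


def compare_partitions(a, b, sample_ids: list[str] | None = None):
    """Adjusted Rand index and contingency table between two partitions
    of the same samples."""
    if isinstance(a, dict) or isinstance(b, dict):
        if isinstance(a, dict) and isinstance(b, dict):
            if set(a) != set(b):
                raise ValidationError("partitions cover different samples")
            ids = sorted(a)
        else:
            if sample_ids is None:
                raise ValidationError("sample_ids required to align dict and array")
            ids = list(sample_ids)
        la = np.array([a[s] for s in ids]) if isinstance(a, dict) else np.asarray(a)
        lb = np.array([b[s] for s in ids]) if isinstance(b, dict) else np.asarray(b)
    else:
        la, lb = np.asarray(a), np.asarray(b)
    if la.shape != lb.shape:
        raise ValidationError("partitions cover different samples")
    ari = float(adjusted_rand_score(la, lb))
    tab = pd.crosstab(pd.Series(la, name="a"), pd.Series(lb, name="b"))
    return {"ari": ari, "cross_tab": tab}


# ----------------------------------------------------------------------
# model / results surface
# ----------------------------------------------------------------------

class Enterotyper:
    """Enterotype model for one kingdom's genus table.

    Parameters
    ----------
    table : AbundanceTable
        Normalized genus-level table (one kingdom).
    metric : {"jsd", "bray_curtis"}
        Sample dissimilarity used for clustering.
    dm : DistanceMatrix, optional
        Precomputed distances (skips recomputation).
    """

    def __init__(self, table: AbundanceTable, metric: str = "jsd",
                 dm: DistanceMatrix | None = None):
        self.table = table
        self.metric = metric
        self.dm = dm if dm is not None else pairwise_distances(table, metric)
        self.embedding = pcoa(self.dm)

    def fit(self, K: int | None = None, K_range=range(2, 9), seed: int = 0
            ) -> "EnterotypeResults":
        """Fit PAM; if ``K`` is None, select it from the validity curves."""
        curve = select_K(self.dm, K_range=K_range, seed=seed,
                         embedding=self.embedding)
        chosen = K if K is not None else curve.chosen_K
        model = curve.models.get(chosen) or pam(self.dm, chosen, seed=seed)
        model = assign_drivers(model, self.table)
        ordination = bca(self.table, model.assignment)
        return EnterotypeResults(self, model, curve, ordination)


@dataclass
class EnterotypeResults:
    model_spec: Enterotyper
    partition: EnterotypeModel
    validity: ValidityCurve
    ordination: BcaResult

    @property
    def K(self) -> int:
        return self.partition.K

    @property
    def assignment(self) -> dict[str, int]:
        return self.partition.assignment

    def summary(self) -> pd.DataFrame:
        """Per-cluster summary: size, medoid, driver genus, driver share."""
        labels = np.array(list(self.partition.assignment.values()))
        rows = []
        for k in range(1, self.K + 1):
            driver = self.partition.driver_taxon.get(k)
            share = (
                float(self.partition.cluster_profiles.loc[k].max())
                if self.partition.cluster_profiles is not None else np.nan
            )
            rows.append({
                "cluster": f"E{k}",
                "n": int((labels == k).sum()),
                "medoid": self.partition.medoid_ids[k - 1],
                "driver": driver.name if driver else None,
                "driver_mean_abundance": share,
            })
        return pd.DataFrame(rows).set_index("cluster")

    def assignment_frame(self, kingdom: str | None = None) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "kingdom": kingdom, "metric": self.partition.metric,
             "K": self.K, "cluster_label": f"E{l}",
             "driver_taxon": self.partition.driver_taxon[l].name}
            for s, l in self.partition.assignment.items()
        ]
        return pd.DataFrame(rows).set_index("sample_id")
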