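"""Pairwise community dissimilarities and principal-coordinates embedding.

Two metrics are provided, both bounded on [0, 1] for compositions:

* Jensen-Shannon distance — the square root of the Jensen-Shannon
  divergence computed with base-2 logarithms, a true metric on
  probability vectors (the canonical enterotyping distance).
* Bray-Curtis — ``1 - sum_i min(p_i, q_i)`` for normalized compositions.

PCoA is classical metric scaling (Torgerson): double-centre ``-D**2/2``,
eigendecompose, keep positive-eigenvalue axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "PcoaEmbedding",
    "jsd_distance",
    "bray_curtis",
    "pairwise_distances",
    "pcoa",
]

_EIG_TOL = 1e-10


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def write(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )

    @classmethod
    def read(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(), metric)


@dataclass
class PcoaEmbedding:
    sample_ids: list[str]
    coordinates: np.ndarray  # n x m, axes by decreasing eigenvalue
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    negative_eigenvalue_magnitude: float = 0.0


def _check_compositions(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("composition vectors differ in length")
    for v, name in ((p, "p"), (q, "q")):
        if (v < 0).any():
            raise ValidationError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} does not sum to 1 (sum={v.sum()!r})")
    return p, q


def jsd_distance(p, q) -> float:
    """Jensen-Shannon distance: sqrt(JSD) with base-2 logs, in [0, 1].

    Terms with zero probability contribute zero (the x*log(x) -> 0 limit);
    the mixture m = (p+q)/2 is nonzero wherever p or q is, so no
    pseudocounts are needed.
    """
    p, q = _check_compositions(p, q)
    m = 0.5 * (p + q)
    div = 0.5 * _kl2(p, m) + 0.5 * _kl2(q, m)
    # clip tiny negatives from rounding
    return float(np.sqrt(max(div, 0.0)))


def _kl2(p: np.ndarray, m: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / m[mask])))


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity 1 - sum(min(p_i, q_i)) on compositions."""
    p, q = _check_compositions(p, q)
    return float(1.0 - np.minimum(p, q).sum())


def pairwise_distances(table: AbundanceTable, metric: str = "jsd") -> DistanceMatrix:
    """Full symmetric sample-by-sample dissimilarity matrix."""
    if not table.normalized:
        raise ValidationError("pairwise_distances requires a normalized table")
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    X = table.matrix()  # samples x taxa
    n = X.shape[0]
    if metric == "jsd":
        D = _pairwise_jsd(X)
    elif metric == "bray_curtis":
        # vectorized 1 - sum(min): via |p-q| identity, sum|p-q| = 2(1-sum min)
        D = np.zeros((n, n))
        for i in range(n):
            D[i] = 0.5 * np.abs(X - X[i]).sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(table.samples, D, metric)


def _pairwise_jsd(X: np.ndarray) -> np.ndarray:
    """JSD distance matrix via entropy identity.

    JSD(p,q) = H2(m) - (H2(p)+H2(q))/2 with base-2 entropies H2.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(X > 0, X * np.log2(np.where(X > 0, X, 1.0)), 0.0)
    H = -plogp.sum(axis=1)  # per-sample entropy
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        M = 0.5 * (X + X[i])
        with np.errstate(divide="ignore", invalid="ignore"):
            mlogm = np.where(M > 0, M * np.log2(np.where(M > 0, M, 1.0)), 0.0)
        Hm = -mlogm.sum(axis=1)
        div = Hm - 0.5 * (H + H[i])
        D[i] = np.sqrt(np.clip(div, 0.0, 1.0))
    return D


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaEmbedding:
    """Classical metric scaling of a distance matrix.

    Negative-eigenvalue axes are discarded; their total magnitude is
    recorded on the embedding. ``variance_explained`` is relative to the
    sum of positive eigenvalues.
    """
    D = dm.values
    n = D.shape[0]
    B = -0.5 * D ** 2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > _EIG_TOL
    neg_mag = float(-evals[evals < 0].sum())
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    if n_axes is not None:
        evals_pos, evecs_pos = evals_pos[:n_axes], evecs_pos[:, :n_axes]
    coords = evecs_pos * np.sqrt(evals_pos)
    total = evals[evals > 0].sum()
    var_exp = evals_pos / total if total > 0 else np.zeros_like(evals_pos)
    return PcoaEmbedding(list(dm.sample_ids), coords, evals_pos, var_exp, neg_mag)
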