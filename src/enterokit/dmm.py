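"""Dirichlet-multinomial mixture (DMM) fitting by EM.

Each sample's taxon count vector is multinomial with probabilities drawn
from one of K Dirichlet components; the model is the canonical
community-typing null against which a PAM partition is checked for
robustness. Fitting maximizes the mixture log-likelihood by EM: exact
posterior responsibilities in the E-step, and in the M-step closed-form
mixture weights plus Minka's fixed-point (an MM step, hence monotone)
for the Dirichlet parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .io import ValidationError

__all__ = [
    "DirichletMultinomialMixture",
    "DMMResults",
    "dmm_fit",
    "counts_from_relative",
]

_ALPHA_FLOOR = 1e-6


def counts_from_relative(proportions: np.ndarray, depth: int = 10_000) -> np.ndarray:
    """Reconstitute integer counts from relative abundances at a fixed
    depth using largest-remainder rounding (each row sums to ``depth``)."""
    P = np.asarray(proportions, dtype=float)
    raw = P * depth
    base = np.floor(raw).astype(int)
    short = depth - base.sum(axis=1)
    rem = raw - base
    out = base.copy()
    for i, s in enumerate(short):
        if s > 0:
            # stable: largest remainders first, ties to lower taxon index
            order = np.lexsort((np.arange(P.shape[1]), -rem[i]))
            out[i, order[:s]] += 1
    return out


def _dm_logpmf(counts: np.ndarray, alpha: np.ndarray, log_coef: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log-pmf of each sample under parameters alpha."""
    A = alpha.sum()
    N = counts.sum(axis=1)
    return (
        log_coef
        + gammaln(A) - gammaln(N + A)
        + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1)
    )


class DirichletMultinomialMixture:
    """K-component Dirichlet-multinomial mixture over integer counts.

    Parameters
    ----------
    counts : (n_samples, n_taxa) nonnegative integer array
    K : number of mixture components (>= 1)
    """

    def __init__(self, counts: np.ndarray, K: int):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D sample x taxa matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        if K < 1:
            raise ValidationError("K must be >= 1")
        self.counts = counts.astype(np.int64)
        self.K = int(K)
        n = self.counts.sum(axis=1)
        self._log_coef = gammaln(n + 1) - gammaln(self.counts + 1).sum(axis=1)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, max_iter: int = 200, tol: float = 1e-4,
            n_init: int = 3, inner_iter: int = 5) -> "DMMResults":
        """EM fit; best of ``n_init`` seeded restarts by log-likelihood."""
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(max(n_init, 1)):
            res = self._fit_once(rng, max_iter, tol, inner_iter)
            if best is None or res.loglik > best.loglik:
                best = res
        return best

    def _init_resp(self, rng: np.random.Generator) -> np.ndarray:
        n = self.counts.shape[0]
        if self.K == 1:
            return np.ones((n, 1))
        # soft random start biased toward a random hard partition
        hard = rng.integers(0, self.K, size=n)
        resp = np.full((n, self.K), 0.1 / max(self.K - 1, 1))
        resp[np.arange(n), hard] = 0.9
        return resp / resp.sum(axis=1, keepdims=True)

    def _fit_once(self, rng, max_iter, tol, inner_iter) -> "DMMResults":
        X = self.counts.astype(float)
        n, t = X.shape
        N = X.sum(axis=1)
        resp = self._init_resp(rng)
        # initial alphas: component-weighted mean proportions, modest concentration
        P = X / np.maximum(N, 1)[:, None]
        alphas = np.empty((self.K, t))
        for k in range(self.K):
            w = resp[:, k] / resp[:, k].sum()
            alphas[k] = np.maximum((w @ P) * t, _ALPHA_FLOOR)
        weights = resp.mean(axis=0)

        logliks: list[float] = []
        converged = False
        for _ in range(max_iter):
            # E-step
            log_comp = np.column_stack([
                _dm_logpmf(X, alphas[k], self._log_coef) for k in range(self.K)
            ])
            log_joint = log_comp + np.log(np.maximum(weights, 1e-300))
            ll = float(logsumexp(log_joint, axis=1).sum())
            logliks.append(ll)
            if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
                converged = True
                break
            resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
            # M-step
            weights = resp.mean(axis=0)
            for k in range(self.K):
                r = resp[:, k]
                if r.sum() < 1e-12:
                    continue
                a = alphas[k]
                for _ in range(inner_iter):
                    A = a.sum()
                    num = (r[:, None] * (digamma(X + a) - digamma(a))).sum(axis=0)
                    den = (r * (digamma(N + A) - digamma(A))).sum()
                    if den <= 0:
                        break
                    a = np.maximum(a * num / den, _ALPHA_FLOOR)
                alphas[k] = a

        log_comp = np.column_stack([
            _dm_logpmf(X, alphas[k], self._log_coef) for k in range(self.K)
        ])
        log_joint = log_comp + np.log(np.maximum(weights, 1e-300))
        ll = float(logsumexp(log_joint, axis=1).sum())
        if not logliks or ll >= logliks[-1]:
            logliks.append(ll)
        resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
        hard = resp.argmax(axis=1) + 1
        p = (self.K - 1) + self.K * t
        bic = -2.0 * logliks[-1] + p * np.log(n)
        return DMMResults(
            model=self, K=self.K, mixture_weights=weights, dirichlet_params=alphas,
            responsibilities=resp, assignment=hard, loglik=logliks[-1],
            loglik_trace=np.array(logliks), bic=float(bic), converged=converged,
        )


@dataclass
class DMMResults:
    model: DirichletMultinomialMixture
    K: int
    mixture_weights: np.ndarray
    dirichlet_params: np.ndarray
    responsibilities: np.ndarray
    assignment: np.ndarray          # 1..K posterior-argmax labels
    loglik: float
    loglik_trace: np.ndarray
    bic: float
    converged: bool

    def summary(self) -> str:
        lines = [
            f"Dirichlet-multinomial mixture, K={self.K}",
            f"  log-likelihood {self.loglik:.3f}   BIC {self.bic:.3f}"
            f"   converged={self.converged}",
            "  component weights: "
            + ", ".join(f"{w:.3f}" for w in self.mixture_weights),
            "  component sizes (argmax): "
            + ", ".join(str(int((self.assignment == k + 1).sum()))
                        for k in range(self.K)),
        ]
        return "\n".join(lines)


def dmm_fit(counts, K: int, seed: int = 0, max_iter: int = 200,
            tol: float = 1e-4, n_init: int = 3) -> DMMResults:
    """Functional wrapper around :class:`DirichletMultinomialMixture`."""
    return DirichletMultinomialMixture(counts, K).fit(
        seed=seed, max_iter=max_iter, tol=tol, n_init=n_init
    )
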