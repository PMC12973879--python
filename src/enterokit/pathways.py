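"""Associating MetaCyc pathway abundances with enterotypes (one-vs-rest
enrichment) and with driver-genus panels (correlation), with BH
multiplicity control within each analysis family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .classify import FeaturePanel
from .io import AbundanceTable, TaxonId, ValidationError
from .stats import bh_fdr, rank_sum_test

__all__ = [
    "PathwayEnrichment",
    "GenusPathwayCorrelation",
    "enrich_pathways",
    "correlate_genus_pathway",
    "cross_kingdom_correlation",
]


@dataclass
class PathwayEnrichment:
    pathway_id: str
    enterotype: int
    log_fc: float
    p: float
    q: float
    retained: bool


@dataclass
class GenusPathwayCorrelation:
    taxon: TaxonId
    pathway_id: str
    rho: float | None
    method: str
    p: float | None
    q: float | None
    retained: bool
    reason: str | None = None  # set when the correlation is undefined


def enrich_pathways(pathways: AbundanceTable, assignment, alpha: float = 0.05,
                    log_base: float = 2.0) -> list[PathwayEnrichment]:
    """One-vs-rest rank-sum enrichment of each pathway in each enterotype.

    log_fc = log2((mean_in + eps) / (mean_out + eps)) with eps half the
    smallest nonzero value in the table; BH correction within each
    enterotype's family; ``retained`` marks q < alpha.
    """
    if isinstance(assignment, dict):
        y = np.array([assignment[s] for s in pathways.samples])
    else:
        y = np.asarray(assignment)
    X = pathways.matrix()  # samples x pathways
    ids = [t.name for t in pathways.taxa]
    nz = X[X > 0]
    eps = 0.5 * nz.min() if nz.size else 1e-12
    out: list[PathwayEnrichment] = []
    for k in sorted(np.unique(y)):
        members = y == k
        if members.sum() < 2:
            continue
        ps, lfcs = [], []
        for j in range(X.shape[1]):
            xin, xout = X[members, j], X[~members, j]
            lfc = np.log((xin.mean() + eps) / (xout.mean() + eps)) / np.log(log_base)
            if np.all(X[:, j] == X[0, j]):
                p = 1.0
            else:
                p = rank_sum_test(xin, xout)["p"]
            ps.append(p)
            lfcs.append(lfc)
        qs = bh_fdr(ps)
        for j in range(X.shape[1]):
            out.append(PathwayEnrichment(
                pathway_id=ids[j], enterotype=int(k), log_fc=float(lfcs[j]),
                p=float(ps[j]), q=float(qs[j]), retained=bool(qs[j] < alpha),
            ))
    return out


def _corr_with_p(x: np.ndarray, y: np.ndarray, method: str):
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None, "zero variance"
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), None


def correlate_genus_pathway(genera: AbundanceTable, pathways: AbundanceTable,
                            panel: FeaturePanel, method: str = "spearman",
                            alpha: float = 0.05, p_adjust: str = "fdr_bh"
                            ) -> list[GenusPathwayCorrelation]:
    """Correlate every (panel genus, pathway) pair across the shared
    samples; BH across all pairs tested; ``retained`` marks q < alpha."""
    if genera.samples != pathways.samples:
        shared = [s for s in genera.samples if s in set(pathways.samples)]
        if not shared:
            raise ValidationError("no shared samples between tables")
        genera = genera.subset_samples(shared)
        pathways = pathways.subset_samples(shared)
    recs = []
    pvals = []
    pw_ids = [t.name for t in pathways.taxa]
    PW = pathways.matrix()
    for t in panel.taxa:
        if tuple(t) not in genera.data.index:
            raise ValidationError(f"panel taxon missing: {t.name}")
        g = genera.data.loc[tuple(t)].to_numpy()
        for j, pid in enumerate(pw_ids):
            rho, p, reason = _corr_with_p(g, PW[:, j], method)
            recs.append([t, pid, rho, p, reason])
            if p is not None:
                pvals.append(p)
    if p_adjust == "fdr_bh":
        qs = iter(bh_fdr(pvals)) if pvals else iter([])
    elif p_adjust == "none":
        qs = iter(pvals)
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    out = []
    for t, pid, rho, p, reason in recs:
        q = float(next(qs)) if p is not None else None
        out.append(GenusPathwayCorrelation(
            taxon=t, pathway_id=pid, rho=rho, method=method, p=p, q=q,
            retained=bool(q is not None and q < alpha), reason=reason,
        ))
    return out


def cross_kingdom_correlation(tables: dict[str, AbundanceTable],
                              panels: dict[str, FeaturePanel],
                              method: str = "spearman", alpha: float = 0.05
                              ) -> list[GenusPathwayCorrelation]:
    """Correlate panel genera between kingdoms (within-kingdom pairs are
    excluded by construction); BH across all between-kingdom pairs."""
    kingdoms = sorted(set(tables) & set(panels))
    if len(kingdoms) < 2:
        raise ValidationError("need at least two kingdoms with tables and panels")
    base = tables[kingdoms[0]].samples
    for k in kingdoms[1:]:
        if tables[k].samples != base:
            raise ValidationError("kingdom tables must share the same samples")
    recs, pvals = [], []
    for a_i in range(len(kingdoms)):
        for b_i in range(a_i + 1, len(kingdoms)):
            ka, kb = kingdoms[a_i], kingdoms[b_i]
            for ta in panels[ka].taxa:
                xa = tables[ka].data.loc[tuple(ta)].to_numpy()
                for tb in panels[kb].taxa:
                    xb = tables[kb].data.loc[tuple(tb)].to_numpy()
                    rho, p, reason = _corr_with_p(xa, xb, method)
                    recs.append([ta, tb.name, rho, p, reason])
                    if p is not None:
                        pvals.append(p)
    qs = iter(bh_fdr(pvals)) if pvals else iter([])
    out = []
    for ta, name_b, rho, p, reason in recs:
        q = float(next(qs)) if p is not None else None
        out.append(GenusPathwayCorrelation(
            taxon=ta, pathway_id=name_b, rho=rho, method=method, p=p, q=q,
            retained=bool(q is not None and q < alpha), reason=reason,
        ))
    return out
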