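"""Random-forest classification of populations from enterotype-derived
genus panels, with grid-searched hyperparameters, a stratified 80/20
split and bootstrap internal validation.

Feature panels are the top-N genera of a chosen enterotype; multi-kingdom
models take the union of per-kingdom panels. The bootstrap resamples the
held-out fold's predictions (internal validation of the fixed model);
refitting per replicate is available via ``refit_bootstrap=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .enterotype import EnterotypeModel
from .io import AbundanceTable, TaxonId, ValidationError

__all__ = [
    "FeaturePanel",
    "ClassifierReport",
    "build_panel",
    "union_panels",
    "train_evaluate",
    "compare_models",
    "DEFAULT_GRID",
]

DEFAULT_GRID = {
    "n_estimators": [200, 500],
    "max_depth": [None, 8],
    "max_features": ["sqrt", 0.5],
}


@dataclass
class FeaturePanel:
    name: str
    taxa: list[TaxonId]
    source: str
    short: bool = False  # fewer taxa available than requested

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("panel taxa must be unique")


@dataclass
class ClassifierReport:
    name: str
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: np.ndarray                  # rows true (neg,pos), cols predicted
    bootstrap_auc: np.ndarray
    importances: dict[str, float]
    best_params: dict
    split_seed: int
    model_seed: int
    pos_label: str
    classes: tuple[str, str]
    test_sample_ids: list[str] = field(default_factory=list)
    y_true: np.ndarray | None = None
    y_score: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            f"Random-forest report: {self.name}",
            f"  AUC {self.auc:.3f}  accuracy {self.accuracy:.3f}  "
            f"F1 {self.f1:.3f}",
            f"  sensitivity {self.sensitivity:.3f}  "
            f"specificity {self.specificity:.3f}  (positive={self.pos_label})",
            f"  bootstrap AUC mean {self.bootstrap_auc.mean():.3f} "
            f"[{np.percentile(self.bootstrap_auc, 2.5):.3f}, "
            f"{np.percentile(self.bootstrap_auc, 97.5):.3f}] "
            f"({len(self.bootstrap_auc)} replicates)",
            "  top features: "
            + ", ".join(
                f"{k} ({v:.3f})"
                for k, v in sorted(self.importances.items(), key=lambda kv: -kv[1])[:5]
            ),
        ]
        return "\n".join(lines)

    def roc_points(self) -> pd.DataFrame:
        fpr, tpr, thr = roc_curve(self.y_true, self.y_score, pos_label=1)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def build_panel(model: EnterotypeModel, table: AbundanceTable, cluster: int = 1,
                top_n: int = 10) -> FeaturePanel:
    """Top ``top_n`` genera by mean relative abundance among samples of one
    enterotype, in decreasing-abundance order (ties lexicographic)."""
    labels = model.labels(table.samples)
    members = labels == cluster
    if members.sum() == 0:
        raise ValidationError(f"cluster {cluster} has no members in table")
    mean = table.data.loc[:, members].mean(axis=1)
    nonzero = mean[mean > 0]
    ordered = sorted(
        nonzero.items(), key=lambda kv: (-kv[1], kv[0][2])
    )
    taxa = [TaxonId(*t) for t, _ in ordered[:top_n]]
    short = len(taxa) < top_n
    driver = model.driver_taxon.get(cluster)
    src = f"top {top_n} genera of E{cluster}" + (f" ({driver.name})" if driver else "")
    return FeaturePanel(name=f"E{cluster}-top{top_n}", taxa=taxa, source=src, short=short)


def union_panels(panels: list[FeaturePanel], name: str | None = None) -> FeaturePanel:
    """Order-preserving union (first occurrence wins)."""
    seen: dict[TaxonId, None] = {}
    for p in panels:
        for t in p.taxa:
            seen.setdefault(t, None)
    return FeaturePanel(
        name=name or "+".join(p.name for p in panels),
        taxa=list(seen),
        source="; ".join(p.source for p in panels),
    )


def _panel_matrix(table: AbundanceTable, panel: FeaturePanel) -> np.ndarray:
    rows = []
    for t in panel.taxa:
        if tuple(t) not in table.data.index:
            raise ValidationError(f"panel taxon missing from table: {t.name}")
        rows.append(table.data.loc[tuple(t)].to_numpy())
    return np.array(rows).T  # samples x features


def train_evaluate(table: AbundanceTable, panel: FeaturePanel, labels,
                   split: float = 0.8, n_boot: int = 100,
                   grid: dict | None = None, seed: int = 0,
                   cv: int = 3, pos_label: str | None = None,
                   refit_bootstrap: bool = False) -> ClassifierReport:
    """Stratified train/test split, grid-searched random forest, held-out
    metrics at probability threshold 0.5, and bootstrap AUC."""
    if isinstance(labels, dict):
        y = np.array([labels[s] for s in table.samples])
    else:
        y = np.asarray(labels)
    classes = sorted(np.unique(y))
    if len(classes) != 2:
        raise ValidationError("train_evaluate requires exactly two classes")
    if pos_label is None:
        pos_label = classes[1]
    neg_label = classes[0] if pos_label == classes[1] else classes[1]
    X = _panel_matrix(table, panel)
    yb = (y == pos_label).astype(int)
    samples = np.array(table.samples)
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, train_size=split, stratify=yb, random_state=seed
    )
    if len(np.unique(yb[tr])) < 2 or len(np.unique(yb[te])) < 2:
        raise ValidationError("a class is absent from a fold; check stratification")

    grid = DEFAULT_GRID if grid is None else grid
    rf = RandomForestClassifier(random_state=seed)
    search = GridSearchCV(
        rf, grid, scoring="roc_auc",
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X[tr], yb[tr])
    model = search.best_estimator_  # already refit on the full training fold

    score = model.predict_proba(X[te])[:, 1]
    pred = (score >= 0.5).astype(int)
    y_te = yb[te]
    cm = confusion_matrix(y_te, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / cm.sum()
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    auc = float(roc_auc_score(y_te, score))

    rng = np.random.default_rng(seed)
    pos_idx = np.where(y_te == 1)[0]
    neg_idx = np.where(y_te == 0)[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rs = np.concatenate([
            rng.choice(pos_idx, size=len(pos_idx), replace=True),
            rng.choice(neg_idx, size=len(neg_idx), replace=True),
        ])
        if refit_bootstrap:
            trb = rng.choice(tr, size=len(tr), replace=True)
            if len(np.unique(yb[trb])) < 2:
                trb = tr
            m = RandomForestClassifier(random_state=seed, **search.best_params_)
            m.fit(X[trb], yb[trb])
            boot[b] = roc_auc_score(y_te[rs], m.predict_proba(X[te][rs])[:, 1])
        else:
            boot[b] = roc_auc_score(y_te[rs], score[rs])

    imp = model.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    importances = {t.name: float(v) for t, v in zip(panel.taxa, imp)}

    return ClassifierReport(
        name=panel.name, auc=auc, accuracy=float(acc), sensitivity=float(sens),
        specificity=float(spec), f1=float(f1), confusion=cm,
        bootstrap_auc=boot, importances=importances,
        best_params=dict(search.best_params_), split_seed=seed, model_seed=seed,
        pos_label=str(pos_label), classes=(str(neg_label), str(pos_label)),
        test_sample_ids=list(samples[te]), y_true=y_te, y_score=score,
    )


def compare_models(reports: dict[str, ClassifierReport], n_boot: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Rank models by mean bootstrap AUC and give paired-bootstrap
    percentile intervals for every pairwise AUC difference.

    All reports must come from the same held-out fold.
    """
    names = sorted(reports)
    ref = reports[names[0]]
    for n in names[1:]:
        r = reports[n]
        if r.test_sample_ids != ref.test_sample_ids or not np.array_equal(
            r.y_true, ref.y_true
        ):
            raise ValidationError("reports were not evaluated on the same test fold")
    y = ref.y_true
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    aucs = {n: np.empty(n_boot) for n in names}
    for b in range(n_boot):
        rs = np.concatenate([
            rng.choice(pos_idx, size=len(pos_idx), replace=True),
            rng.choice(neg_idx, size=len(neg_idx), replace=True),
        ])
        for n in names:
            aucs[n][b] = roc_auc_score(y[rs], reports[n].y_score[rs])
    rows = []
    for n in names:
        for m in names:
            if m <= n:
                continue
            diff = aucs[n] - aucs[m]
            rows.append({
                "model_a": n, "model_b": m,
                "mean_auc_a": float(aucs[n].mean()),
                "mean_auc_b": float(aucs[m].mean()),
                "auc_diff": float(diff.mean()),
                "ci_low": float(np.percentile(diff, 2.5)),
                "ci_high": float(np.percentile(diff, 97.5)),
            })
    out = pd.DataFrame(rows)
    ranking = sorted(names, key=lambda n: -aucs[n].mean())
    out.attrs["ranking"] = ranking
    return out
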