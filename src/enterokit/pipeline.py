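"""End-to-end orchestration: ingest -> filter -> per-kingdom distances ->
enterotyping (validity curves, BCA, optional DMM check) -> differential
features -> pathway association -> feature panels -> classifiers ->
manifest.

Stage outputs are plain TSV/JSON files in a flat run directory; the
manifest records the config snapshot and a sha256 checksum for every
emitted file, and is itself deterministic for a fixed config (wall-clock
notes go to ``run.log``, not into the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import FeaturePanel, build_panel, train_evaluate, union_panels
from .distance import pairwise_distances
from .dmm import counts_from_relative, dmm_fit
from .enterotype import Enterotyper, compare_partitions
from .io import (AbundanceTable, ValidationError, filter_low_prevalence,
                 filter_rare_taxa, metadata_frame, read_abundance_table,
                 read_metadata, renormalize, split_by_kingdom)
from .pathways import correlate_genus_pathway, cross_kingdom_correlation, enrich_pathways
from .simulate import generate_cohort, preset_study_architecture
from .stats import lefse_screen, permanova

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "TASKS"]

# comparison task -> (subgroups kept or None for all, label column)
TASKS = {
    "hp-vs-cp": (None, "region"),
    "hap-vs-hhp": ({"HAP", "HHP"}, "subgroup"),
    "hap-vs-hcp": ({"HAP", "HHP"}, "subgroup"),   # alias: HCP == healthy HP
    "hap-vs-cap": ({"HAP", "CAP"}, "subgroup"),
}


@dataclass
class RunConfig:
    outdir: str
    seed: int
    # either real inputs ...
    abundance_path: str | None = None
    pathways_path: str | None = None
    metadata_path: str | None = None
    # ... or the synthetic preset
    synthetic_preset: bool = False
    n_per_subgroup: dict | None = None
    depth: int = 30_000
    # enterotyping
    metric: str = "jsd"
    K_range: list[int] = field(default_factory=lambda: list(range(2, 9)))
    pinned_K: dict = field(default_factory=dict)        # kingdom -> K
    rare_floor: float = 1e-4
    prevalence_min: int = 10
    dmm_enabled: bool = False
    dmm_depth: int = 10_000
    # testing / classification
    comparisons: list[str] = field(default_factory=lambda: ["hp-vs-cp"])
    lda_threshold: float = 2.0
    alpha: float = 0.05
    top_n: int = 10
    classifier_grid: dict | None = None
    n_boot: int = 100
    permanova_permutations: int = 999

    def validate(self) -> None:
        real = all(p is not None for p in
                   (self.abundance_path, self.metadata_path))
        if not real and not self.synthetic_preset:
            raise ValidationError(
                "config needs either input paths (abundance_path, metadata_path) "
                "or synthetic_preset=true"
            )
        for c in self.comparisons:
            if c not in TASKS:
                raise ValidationError(f"unknown comparison task {c!r}")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, list[dict]] = field(default_factory=dict)
    counts: dict[str, dict] = field(default_factory=dict)

    def add(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.stages.setdefault(stage, []).append(
            {"file": path.name, "sha256": digest}
        )

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "counts": self.counts,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _log(logf, msg: str) -> None:
    logf.write(f"{time.strftime('%H:%M:%S')} {msg}\n")
    logf.flush()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; each stage writes its outputs before the
    next starts. Rerunning with the same config reproduces identical
    checksums."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        version=__version__,
    )
    logf = open(outdir / "run.log", "w")
    t0 = time.time()
    try:
        # ---- ingest ---------------------------------------------------
        stage = "ingest"
        if config.synthetic_preset:
            spec = preset_study_architecture(
                seed=config.seed,
                n_per_subgroup=config.n_per_subgroup,
                depth=config.depth,
            )
            cohort = generate_cohort(spec)
            tables = cohort.tables
            pathway_table = cohort.pathway_table
            meta = cohort.meta
        else:
            table = read_abundance_table(config.abundance_path)
            table = renormalize(table)
            tables = split_by_kingdom(table)
            meta = read_metadata(config.metadata_path)
            from .io import read_pathway_table
            pathway_table = (
                read_pathway_table(config.pathways_path)
                if config.pathways_path else None
            )
        meta_df = metadata_frame(meta)
        p = outdir / "metadata.tsv"
        meta_df.to_csv(p, sep="\t")
        manifest.add(stage, p)
        manifest.counts[stage] = {"n_samples": len(meta_df),
                                  "kingdoms": sorted(tables)}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        # ---- filter ---------------------------------------------------
        stage = "filter"
        filtered: dict[str, AbundanceTable] = {}
        for k in sorted(tables):
            ft = filter_rare_taxa(tables[k], floor=config.rare_floor)
            filtered[k] = ft
            p = outdir / f"filtered_{k}.tsv"
            ft.write(p)
            manifest.add(stage, p)
        manifest.counts[stage] = {k: filtered[k].n_taxa for k in sorted(filtered)}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        # ---- distances + enterotyping --------------------------------
        stage = "enterotype"
        results = {}
        dms = {}
        for k in sorted(filtered):
            dm = pairwise_distances(filtered[k], config.metric)
            dms[k] = dm
            p = outdir / f"distance_{k}.tsv"
            dm.write(p)
            manifest.add("distance", p)
            et = Enterotyper(filtered[k], metric=config.metric, dm=dm)
            res = et.fit(K=config.pinned_K.get(k), K_range=config.K_range,
                         seed=config.seed)
            results[k] = res
            p = outdir / f"enterotypes_{k}.tsv"
            res.assignment_frame(kingdom=k).to_csv(p, sep="\t")
            manifest.add(stage, p)
            p = outdir / f"validity_{k}.tsv"
            res.validity.frame().to_csv(p, sep="\t", float_format="%.10g")
            manifest.add(stage, p)
            if config.dmm_enabled:
                counts = counts_from_relative(filtered[k].matrix(), config.dmm_depth)
                fit = dmm_fit(counts, res.K, seed=config.seed)
                cmp = compare_partitions(
                    res.partition.labels(filtered[k].samples), fit.assignment
                )
                p = outdir / f"dmm_{k}.json"
                p.write_text(json.dumps(
                    {"K": res.K, "bic": fit.bic, "loglik": fit.loglik,
                     "ari_vs_pam": cmp["ari"], "converged": fit.converged},
                    indent=1, sort_keys=True) + "\n")
                manifest.add(stage, p)
        manifest.counts[stage] = {k: results[k].K for k in sorted(results)}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        # ---- differential features per comparison ---------------------
        stage = "differential"
        rows = []
        for task in config.comparisons:
            subset, column = TASKS[task]
            keep = meta_df.index if subset is None else meta_df.index[
                meta_df["subgroup"].isin(subset)]
            labels = meta_df.loc[keep, column].to_dict()
            for k in sorted(filtered):
                sub = renormalize(filtered[k].subset_samples(list(keep)))
                feats = lefse_screen(
                    sub, labels, alpha=config.alpha,
                    lda_threshold=config.lda_threshold, seed=config.seed,
                )
                for f in feats:
                    rows.append({
                        "comparison": task, "kingdom": k, "taxon": f.taxon.name,
                        "statistic": f.statistic, "p": f.p, "q": f.q,
                        "lda_score": f.lda_score, "enriched_in": f.enriched_in,
                    })
                pr = permanova(
                    pairwise_distances(sub, "bray_curtis"),
                    labels, n_perm=config.permanova_permutations,
                    seed=config.seed,
                )
                rows.append({
                    "comparison": task, "kingdom": k, "taxon": "(PERMANOVA)",
                    "statistic": pr.pseudo_F, "p": pr.p, "q": pr.R2,
                    "lda_score": float("nan"), "enriched_in": "",
                })
        p = outdir / "differential_features.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
        manifest.add(stage, p)
        manifest.counts[stage] = {"n_records": len(rows)}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        # ---- panels ---------------------------------------------------
        stage = "panels"
        panels: dict[str, FeaturePanel] = {}
        for k in sorted(results):
            res = results[k]
            labels_arr = res.partition.labels(filtered[k].samples)
            hp = (meta_df.loc[filtered[k].samples, "region"] == "HP").to_numpy()
            # the study's panel enterotypes are the high-altitude-enriched ones
            frac = [
                hp[labels_arr == c].mean() if (labels_arr == c).sum() else 0.0
                for c in range(1, res.K + 1)
            ]
            cluster = int(np.argmax(frac)) + 1
            panels[k] = build_panel(res.partition, filtered[k],
                                    cluster=cluster, top_n=config.top_n)
        p = outdir / "panels.json"
        p.write_text(json.dumps(
            {k: {"name": v.name, "source": v.source,
                 "taxa": [t.name for t in v.taxa]} for k, v in panels.items()},
            indent=1, sort_keys=True) + "\n")
        manifest.add(stage, p)
        manifest.counts[stage] = {k: len(v.taxa) for k, v in panels.items()}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        # ---- pathway association -------------------------------------
        stage = "pathways"
        if pathway_table is not None:
            pt = pathway_table
            try:
                pt = filter_low_prevalence(pt, config.prevalence_min)
            except ValueError:
                pass
            bact = sorted(results)[0] if "bacteria" not in results else "bacteria"
            enr = enrich_pathways(pt, results[bact].assignment, alpha=config.alpha)
            p = outdir / "pathway_enrichment.tsv"
            pd.DataFrame([dataclasses.asdict(e) for e in enr]).to_csv(
                p, sep="\t", index=False, float_format="%.10g")
            manifest.add(stage, p)
            cors = correlate_genus_pathway(filtered[bact], pt, panels[bact],
                                           method="spearman", alpha=config.alpha)
            p = outdir / "genus_pathway_correlation.tsv"
            pd.DataFrame([
                {"taxon": c.taxon.name, "pathway": c.pathway_id, "rho": c.rho,
                 "method": c.method, "p": c.p, "q": c.q, "retained": c.retained}
                for c in cors
            ]).to_csv(p, sep="\t", index=False, float_format="%.10g")
            manifest.add(stage, p)
            if len(panels) >= 2:
                xk = cross_kingdom_correlation(filtered, panels, method="spearman",
                                               alpha=config.alpha)
                p = outdir / "cross_kingdom_correlation.tsv"
                pd.DataFrame([
                    {"taxon_a": c.taxon.name, "taxon_b": c.pathway_id,
                     "rho": c.rho, "p": c.p, "q": c.q, "retained": c.retained}
                    for c in xk
                ]).to_csv(p, sep="\t", index=False, float_format="%.10g")
                manifest.add(stage, p)
            manifest.counts[stage] = {"n_pathways": pt.n_taxa}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        # ---- classifiers ---------------------------------------------
        stage = "classify"
        merged = _merged_table(filtered)
        reports = {}
        for task in config.comparisons:
            subset, column = TASKS[task]
            keep = list(meta_df.index if subset is None else meta_df.index[
                meta_df["subgroup"].isin(subset)])
            sub = merged.subset_samples(keep)
            labels = meta_df.loc[keep, column].to_dict()
            task_panels = dict(panels)
            task_panels["union"] = union_panels(list(panels.values()), name="union")
            ks = sorted(panels)
            for a_i in range(len(ks)):
                for b_i in range(a_i + 1, len(ks)):
                    pair = union_panels([panels[ks[a_i]], panels[ks[b_i]]],
                                        name=f"{ks[a_i]}+{ks[b_i]}")
                    task_panels[pair.name] = pair
            for pname, panel in sorted(task_panels.items()):
                rep = train_evaluate(
                    sub, panel, labels, n_boot=config.n_boot,
                    grid=config.classifier_grid, seed=config.seed,
                )
                reports[f"{task}:{pname}"] = rep
        p = outdir / "classifier_reports.json"
        p.write_text(json.dumps({
            name: {
                "auc": r.auc, "accuracy": r.accuracy, "f1": r.f1,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "bootstrap_auc_mean": float(r.bootstrap_auc.mean()),
                "confusion": r.confusion.tolist(),
                "best_params": {k: str(v) for k, v in r.best_params.items()},
                "importances": r.importances,
            } for name, r in reports.items()
        }, indent=1, sort_keys=True) + "\n")
        manifest.add(stage, p)
        manifest.counts[stage] = {"n_models": len(reports)}
        _log(logf, f"{stage} done ({time.time() - t0:.1f}s)")

        mpath = outdir / "manifest.json"
        manifest.write(mpath)
        return manifest
    except Exception as exc:
        _log(logf, f"FAILED at stage {stage!r}: {exc}")
        manifest.counts["failed_stage"] = {"stage": stage, "error": str(exc)}
        manifest.write(outdir / "manifest.json")
        raise
    finally:
        logf.close()


def _merged_table(tables: dict[str, AbundanceTable]) -> AbundanceTable:
    """Stack per-kingdom tables (shared samples) without renormalizing
    across kingdoms: panel features keep their within-kingdom scale."""
    ks = sorted(tables)
    df = pd.concat([tables[k].data for k in ks], axis=0)
    return AbundanceTable(df, normalized=False)
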