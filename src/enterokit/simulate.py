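"""Synthetic multi-kingdom cohort generator.

Generates ground-truth-labelled cohorts with the statistical structure
the enterotyping analysis assumes: for each sample a subgroup-dependent
enterotype is drawn per kingdom, a genus composition is drawn from that
enterotype's Dirichlet component (driver genus boosted over a shared
power-law base profile), and integer counts are drawn multinomially at a
per-kingdom sequencing depth. Pathway abundances are linear combinations
of selected genus abundances plus Gaussian noise over a random
background, emulating functional profiles coupled to community
composition.

The default preset mirrors the study architecture: 295 samples in four
subgroups (CHP 78, HHP 68, CAP 106, HAP 43), kingdom read fractions of
roughly 97% bacteria / 0.01% fungi / 0.08% archaea, two bacterial
(Prevotella-, Bacteroides-driven), two fungal (Saccharomyces-,
Malassezia-driven) and three archaeal (Methanobrevibacter-,
Methanosarcina-, Methanosphaera-driven) enterotypes, with the
high-altitude subgroups skewed toward E1/E3/E5.

All randomness flows from one integer seed through per-sample
SeedSequence substreams, so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import AbundanceTable, SampleMeta, TaxonId, ValidationError

__all__ = [
    "EnterotypeSpec",
    "KingdomSpec",
    "PathwaySpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "preset_study_architecture",
    "inject_group_signal",
]

SUBGROUPS = ("CHP", "HHP", "CAP", "HAP")
_REGION = {"CHP": "CP", "CAP": "CP", "HHP": "HP", "HAP": "HP"}
MIN_KINGDOM_DEPTH = 200


@dataclass
class EnterotypeSpec:
    driver: str                      # taxon name receiving the boost
    driver_alpha_boost: float
    base_alpha: float | np.ndarray   # scalar or per-taxon Dirichlet base

    def alphas(self, taxa: list[str]) -> np.ndarray:
        base = np.broadcast_to(np.asarray(self.base_alpha, float), (len(taxa),)).copy()
        if (base <= 0).any() or self.driver_alpha_boost < 0:
            raise ValidationError("Dirichlet parameters must be positive")
        if self.driver not in taxa:
            raise ValidationError(f"driver {self.driver!r} not among taxa")
        base[taxa.index(self.driver)] += self.driver_alpha_boost
        return base


@dataclass
class KingdomSpec:
    taxa: list[str]
    enterotypes: list[EnterotypeSpec]
    mixing: dict[str, list[float]]   # subgroup -> enterotype probabilities

    def validate(self) -> None:
        K = len(self.enterotypes)
        for sg in SUBGROUPS:
            if sg not in self.mixing:
                raise ValidationError(f"mixing missing subgroup {sg}")
            v = np.asarray(self.mixing[sg], float)
            if len(v) != K or abs(v.sum() - 1) > 1e-9 or (v < 0).any():
                raise ValidationError(f"invalid mixing vector for {sg}")


@dataclass
class PathwaySpec:
    pathway_id: str
    sources: list[tuple[str, str]]   # (kingdom, taxon name)
    weights: list[float]
    noise_sd: float = 0.0


@dataclass
class CohortSpec:
    n_per_subgroup: dict[str, int]
    kingdoms: dict[str, KingdomSpec]
    depth: int = 30_000
    kingdom_fractions: dict[str, float] = field(
        default_factory=lambda: {"bacteria": 0.97, "fungi": 1e-4, "archaea": 8e-4}
    )
    pathways: list[PathwaySpec] = field(default_factory=list)
    n_background_pathways: int = 20
    seed: int = 0

    def validate(self) -> None:
        if sum(self.kingdom_fractions.values()) > 1 + 1e-9:
            raise ValidationError("kingdom fractions exceed 1")
        for k, ks in self.kingdoms.items():
            ks.validate()
            if self.kingdom_depth(k) <= 0:
                raise ValidationError(f"zero depth for kingdom {k}")

    def kingdom_depth(self, kingdom: str) -> int:
        raw = int(np.ceil(self.depth * self.kingdom_fractions.get(kingdom, 0.0)))
        return max(raw, MIN_KINGDOM_DEPTH)

    def to_yaml(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if hasattr(o, "__dict__"):
                return conv(vars(o))
            return o
        return yaml.safe_dump(conv(self), sort_keys=True)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    tables: dict[str, AbundanceTable]
    counts: dict[str, np.ndarray]        # kingdom -> taxa x samples int matrix
    pathway_table: AbundanceTable
    meta: list[SampleMeta]
    truth_enterotype: dict[str, dict[str, int]]   # kingdom -> sample -> 1..K
    truth_driver: dict[str, dict[int, str]]       # kingdom -> label -> driver
    injected: list[dict] = field(default_factory=list)
    single_cluster_kingdoms: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    def labels(self, kingdom: str) -> np.ndarray:
        t = self.truth_enterotype[kingdom]
        return np.array([t[s] for s in self.samples])

    def metadata_frame(self) -> pd.DataFrame:
        rows = [(m.sample_id, m.region, m.subgroup, m.age, m.sex) for m in self.meta]
        return pd.DataFrame(
            rows, columns=["sample_id", "region", "subgroup", "age", "sex"]
        ).set_index("sample_id")

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, tab in self.tables.items():
            tab.write(outdir / f"abundance_{k}.tsv")
        self.pathway_table.write(outdir / "pathways.tsv")
        self.metadata_frame().to_csv(outdir / "metadata.tsv", sep="\t")
        truth = {
            "enterotype": self.truth_enterotype,
            "drivers": {k: {str(l): d for l, d in v.items()}
                        for k, v in self.truth_driver.items()},
            "injected": self.injected,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        (outdir / "cohort_spec.yaml").write_text(self.spec.to_yaml())


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, sample_index)))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full labelled cohort from ``spec``."""
    spec.validate()
    meta: list[SampleMeta] = []
    i = 0
    for sg in SUBGROUPS:
        for _ in range(spec.n_per_subgroup.get(sg, 0)):
            meta.append(SampleMeta(f"S{i + 1:04d}", _REGION[sg], sg))
            i += 1
    n = len(meta)
    kingdoms = sorted(spec.kingdoms)
    depths = {k: spec.kingdom_depth(k) for k in kingdoms}

    counts = {k: np.zeros((len(spec.kingdoms[k].taxa), n), dtype=np.int64)
              for k in kingdoms}
    truth: dict[str, dict[str, int]] = {k: {} for k in kingdoms}
    for si, m in enumerate(meta):
        rng = _sample_rng(spec.seed, si)
        for k in kingdoms:
            ks = spec.kingdoms[k]
            mix = np.asarray(ks.mixing[m.subgroup], float)
            e = int(rng.choice(len(ks.enterotypes), p=mix))
            truth[k][m.sample_id] = e + 1
            comp = rng.dirichlet(ks.enterotypes[e].alphas(ks.taxa))
            counts[k][:, si] = rng.multinomial(depths[k], comp)

    tables: dict[str, AbundanceTable] = {}
    for k in kingdoms:
        df = pd.DataFrame(
            counts[k] / depths[k],
            index=pd.MultiIndex.from_tuples(
                [(k, "genus", t) for t in spec.kingdoms[k].taxa],
                names=["kingdom", "rank", "name"],
            ),
            columns=[m.sample_id for m in meta],
        )
        tables[k] = AbundanceTable(df, normalized=True)

    pathway_table = _generate_pathways(spec, tables, n)

    drivers = {
        k: {e + 1: et.driver for e, et in enumerate(spec.kingdoms[k].enterotypes)}
        for k in kingdoms
    }
    degenerate = [
        k for k in kingdoms
        if all(np.asarray(spec.kingdoms[k].mixing[sg]).max() == 1.0 for sg in SUBGROUPS
               if spec.n_per_subgroup.get(sg, 0) > 0)
        and len({int(np.asarray(spec.kingdoms[k].mixing[sg]).argmax())
                 for sg in SUBGROUPS if spec.n_per_subgroup.get(sg, 0) > 0}) == 1
    ]
    return SyntheticCohort(
        spec=spec, tables=tables, counts=counts, pathway_table=pathway_table,
        meta=meta, truth_enterotype=truth, truth_driver=drivers,
        single_cluster_kingdoms=degenerate,
    )


def _generate_pathways(spec: CohortSpec, tables, n: int) -> AbundanceTable:
    sample_ids = tables[next(iter(tables))].samples
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 10 ** 9)))
    rows, ids = [], []
    for ps in spec.pathways:
        v = np.zeros(n)
        for (kingdom, taxon), w in zip(ps.sources, ps.weights):
            if kingdom not in tables:
                raise ValidationError(f"pathway source kingdom {kingdom!r} missing")
            key = (kingdom, "genus", taxon)
            if key not in tables[kingdom].data.index:
                raise ValidationError(f"pathway source taxon {taxon!r} missing")
            v = v + w * tables[kingdom].data.loc[key].to_numpy()
        if ps.noise_sd > 0:
            v = v + rng.normal(0, ps.noise_sd, size=n)
        rows.append(np.maximum(v, 0.0))
        ids.append(ps.pathway_id)
    for b in range(spec.n_background_pathways):
        rows.append(rng.lognormal(mean=-4.0, sigma=1.0, size=n))
        ids.append(f"PWY-SYN-BG{b + 1:04d}")
    M = np.array(rows)
    sums = M.sum(axis=0)
    sums[sums == 0] = 1.0
    df = pd.DataFrame(
        M / sums,
        index=pd.MultiIndex.from_tuples(
            [("pathway", "pathway", pid) for pid in ids],
            names=["kingdom", "rank", "name"],
        ),
        columns=sample_ids,
    )
    return AbundanceTable(df, normalized=True)


# ----------------------------------------------------------------------
# preset mirroring the study architecture
# ----------------------------------------------------------------------

def _power_law_base(n_taxa: int, total: float, exponent: float = 0.7) -> np.ndarray:
    w = np.arange(1, n_taxa + 1, dtype=float) ** -exponent
    return total * w / w.sum()


def _boost_for_share(base: np.ndarray, driver_idx: int, share: float) -> float:
    A = base.sum()
    return (share * A - base[driver_idx]) / (1.0 - share)


def _kingdom_preset(prefix: str, drivers_shares: list[tuple[str, float]],
                    n_taxa: int, total_alpha: float,
                    mixing: dict[str, list[float]]) -> KingdomSpec:
    taxa = [d for d, _ in drivers_shares]
    taxa += [f"{prefix}_g{j:02d}" for j in range(1, n_taxa - len(taxa) + 1)]
    base = _power_law_base(n_taxa, total_alpha)
    ents = []
    for i, (driver, share) in enumerate(drivers_shares):
        boost = _boost_for_share(base, i, share)
        ents.append(EnterotypeSpec(driver=driver, driver_alpha_boost=boost,
                                   base_alpha=base))
    return KingdomSpec(taxa=taxa, enterotypes=ents, mixing=mixing)


def preset_study_architecture(seed: int = 0, n_per_subgroup: dict[str, int] | None = None,
                              depth: int = 30_000) -> CohortSpec:
    """Default cohort spec: 295 samples (CHP 78 / HHP 68 / CAP 106 / HAP 43),
    seven enterotypes across three kingdoms with the reported driver
    dominances (E1 Prevotella 47%, E2 Bacteroides 25%, E3 Saccharomyces
    85%, E4 Malassezia 16%, E5 Methanobrevibacter 80%, E6 Methanosarcina
    31%, E7 Methanosphaera 87%) and the reported high-altitude skew of
    E1 (41.4% vs 18.5%), E3 (27.0% vs 18.5%) and E5 (29.7% vs 26.6%).
    Mixing mass not pinned by those percentages is split in proportion to
    the reported enterotype sizes."""
    if n_per_subgroup is None:
        n_per_subgroup = {"CHP": 78, "HHP": 68, "CAP": 106, "HAP": 43}

    bact_mix = {"CP": [0.185, 0.815], "HP": [0.414, 0.586]}
    fung_mix = {"CP": [0.185, 0.815], "HP": [0.270, 0.730]}
    # archaeal E6:E7 split proportional to reported sizes 62:151
    q6 = 62 / 213
    arch_mix = {
        "CP": [0.266, (1 - 0.266) * q6, (1 - 0.266) * (1 - q6)],
        "HP": [0.297, (1 - 0.297) * q6, (1 - 0.297) * (1 - q6)],
    }
    by_subgroup = lambda mix: {sg: mix[_REGION[sg]] for sg in SUBGROUPS}

    kingdoms = {
        "bacteria": _kingdom_preset(
            "Bact", [("Prevotella", 0.47), ("Bacteroides", 0.25)],
            n_taxa=60, total_alpha=80.0, mixing=by_subgroup(bact_mix)),
        "fungi": _kingdom_preset(
            "Fung", [("Saccharomyces", 0.85), ("Malassezia", 0.16)],
            n_taxa=30, total_alpha=25.0, mixing=by_subgroup(fung_mix)),
        "archaea": _kingdom_preset(
            "Arch", [("Methanobrevibacter", 0.80), ("Methanosarcina", 0.31),
                     ("Methanosphaera", 0.87)],
            n_taxa=25, total_alpha=15.0, mixing=by_subgroup(arch_mix)),
    }
    pathways = [
        PathwaySpec("PWY-SYN-PREVOTELLA", [("bacteria", "Prevotella")], [2.0], 0.01),
        PathwaySpec("PWY-SYN-BACTEROIDES", [("bacteria", "Bacteroides")], [1.5], 0.01),
        PathwaySpec("PWY-SYN-SACCHAROMYCES", [("fungi", "Saccharomyces")], [1.0], 0.01),
        PathwaySpec("PWY-SYN-METHANOGEN",
                    [("archaea", "Methanobrevibacter"), ("archaea", "Methanosphaera")],
                    [1.0, 0.5], 0.01),
    ]
    return CohortSpec(
        n_per_subgroup=dict(n_per_subgroup), kingdoms=kingdoms, depth=depth,
        pathways=pathways, seed=seed,
    )


def inject_group_signal(cohort: SyntheticCohort, taxa: list[tuple[str, str]],
                        effect: float, target: set[str] | list[str]) -> SyntheticCohort:
    """Multiply selected (kingdom, taxon) abundances by ``effect`` in
    samples of the target subgroups, renormalize, and re-derive counts
    deterministically (largest-remainder at the kingdom depth)."""
    from .dmm import counts_from_relative

    if effect <= 0:
        raise ValidationError("effect must be positive")
    if effect == 1.0:
        return cohort
    target = set(target)
    sel = np.array([m.subgroup in target for m in cohort.meta])
    new_tables = dict(cohort.tables)
    new_counts = dict(cohort.counts)
    by_kingdom: dict[str, list[str]] = {}
    for kingdom, name in taxa:
        if kingdom not in cohort.tables:
            raise ValidationError(f"unknown kingdom {kingdom!r}")
        if (kingdom, "genus", name) not in cohort.tables[kingdom].data.index:
            raise ValidationError(f"unknown taxon {name!r} in {kingdom}")
        by_kingdom.setdefault(kingdom, []).append(name)
    for kingdom, names in by_kingdom.items():
        df = cohort.tables[kingdom].data.copy()
        for name in names:
            row = df.loc[(kingdom, "genus", name)].to_numpy()
            row = np.where(sel, row * effect, row)
            df.loc[(kingdom, "genus", name)] = row
        df = df.div(df.sum(axis=0), axis=1)
        depth = cohort.spec.kingdom_depth(kingdom)
        counts = counts_from_relative(df.to_numpy().T, depth).T
        new_counts[kingdom] = counts
        # tables stay consistent with counts (quantized at the kingdom depth)
        new_tables[kingdom] = AbundanceTable(
            pd.DataFrame(counts / depth, index=df.index, columns=df.columns),
            normalized=True,
        )
    injected = cohort.injected + [
        {"taxa": [list(t) for t in taxa], "effect": effect, "target": sorted(target)}
    ]
    return SyntheticCohort(
        spec=cohort.spec, tables=new_tables, counts=new_counts,
        pathway_table=cohort.pathway_table, meta=cohort.meta,
        truth_enterotype=cohort.truth_enterotype, truth_driver=cohort.truth_driver,
        injected=injected, single_cluster_kingdoms=cohort.single_cluster_kingdoms,
    )
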