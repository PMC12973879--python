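"""Reading, validation, filtering and partitioning of multi-kingdom
genus-level relative-abundance tables.

The canonical in-memory container is :class:`AbundanceTable`: a pandas
DataFrame with one row per taxon (indexed by ``(kingdom, rank, name)``)
and one column per sample, holding relative abundances (fractions).
All downstream distance and clustering code assumes each sample column
is a composition (sums to 1), which the filter operations re-establish
after dropping rows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Kingdom",
    "TaxonId",
    "SampleMeta",
    "AbundanceTable",
    "read_abundance_table",
    "read_metadata",
    "renormalize",
    "filter_rare_taxa",
    "filter_low_prevalence",
    "split_by_kingdom",
]

NORM_TOL = 1e-9


class Kingdom(str, enum.Enum):
    BACTERIA = "bacteria"
    FUNGI = "fungi"
    ARCHAEA = "archaea"


class TaxonId(NamedTuple):
    kingdom: str
    rank: str
    name: str


# MetaPhlAn-style lineage prefixes at the domain level
_KINGDOM_PREFIXES = {
    "bacteria": "bacteria",
    "fungi": "fungi",
    "eukaryota": "fungi",  # fungal genera sit under k__Eukaryota in some dialects
    "archaea": "archaea",
}

_RANK_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                  "f": "family", "g": "genus", "s": "species"}


class FormatError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample study metadata.

    ``region`` is CP (coastal) or HP (high altitude); ``subgroup`` is one of
    CHP/HHP (healthy) or CAP/HAP (adenoma). The subgroup determines the
    region: C* samples are coastal, H* samples high-altitude.
    """

    sample_id: str
    region: str
    subgroup: str
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.region not in ("CP", "HP"):
            raise ValidationError(f"unknown region {self.region!r}")
        if self.subgroup not in ("CHP", "HHP", "CAP", "HAP"):
            raise ValidationError(f"unknown subgroup {self.subgroup!r}")
        expected = "CP" if self.subgroup.startswith("C") else "HP"
        if self.region != expected:
            raise ValidationError(
                f"subgroup {self.subgroup} inconsistent with region {self.region}"
            )


@dataclass
class AbundanceTable:
    """Samples-by-taxa compositional matrix.

    ``data`` is taxa (rows) x samples (columns); row index is a MultiIndex
    of (kingdom, rank, name).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValidationError("negative abundance value")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate taxa")
        if self.normalized:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=NORM_TOL, rtol=0):
                raise ValidationError("normalized flag set but columns do not sum to 1")

    # -- basic accessors -------------------------------------------------
    @property
    def taxa(self) -> list[TaxonId]:
        return [TaxonId(*t) for t in self.data.index]

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    def matrix(self) -> np.ndarray:
        """Samples x taxa array (rows are compositions)."""
        return self.data.to_numpy().T

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise ValidationError(f"unknown samples: {sorted(missing)}")
        return AbundanceTable(self.data[ids].copy(), normalized=self.normalized)

    def write(self, path) -> None:
        """Write as TSV: taxon lineage-style first column, samples as header."""
        out = self.data.copy()
        out.index = [f"{k}|{r}__{n}" for k, r, n in self.data.index]
        out.index.name = "taxon"
        out.to_csv(path, sep="\t", float_format="%.17g")


def _parse_taxon(label: str, kingdom_map: Mapping[str, str] | None) -> TaxonId:
    """Parse a MetaPhlAn-style lineage or the writer's compact dialect."""
    label = label.strip()
    if not label:
        raise FormatError("empty taxon label")
    if "|" in label:
        parts = label.split("|")
        kingdom = None
        for part in parts:
            if part.startswith("k__") or part.startswith("d__"):
                kname = part[3:].lower()
                if kname in _KINGDOM_PREFIXES:
                    kingdom = _KINGDOM_PREFIXES[kname]
                elif kingdom_map and part[3:] in kingdom_map:
                    kingdom = kingdom_map[part[3:]]
            elif "__" not in part and part.lower() in ("bacteria", "fungi",
                                                       "archaea", "pathway"):
                kingdom = part.lower()
        last = parts[-1]
        if "__" in last:
            prefix, _, name = last.partition("__")
            pl = prefix.lower()
            if pl in _RANK_PREFIXES:
                rank = _RANK_PREFIXES[pl]
            elif pl in _RANK_PREFIXES.values() or pl == "pathway":
                rank = pl
            else:
                raise FormatError(f"unknown rank prefix {prefix!r} in {label!r}")
        else:
            rank, name = "genus", last
        if kingdom is None:
            raise ValidationError(f"cannot resolve kingdom for {label!r}")
        if not name:
            raise FormatError(f"empty taxon name in {label!r}")
        return TaxonId(kingdom, rank, name)
    # plain name: kingdom must come from kingdom_map
    name = label
    rank = "genus"
    if "__" in label:
        prefix, _, rest = label.partition("__")
        if prefix.lower() in _RANK_PREFIXES:
            rank, name = _RANK_PREFIXES[prefix.lower()], rest
    if kingdom_map is None or name not in kingdom_map:
        raise ValidationError(f"kingdom unknown for plain taxon {name!r}; provide kingdom_map")
    return TaxonId(kingdom_map[name], rank, name)


def read_abundance_table(path, kingdom_map: Mapping[str, str] | None = None,
                         normalized: bool | None = None) -> AbundanceTable:
    """Read a merged MetaPhlAn-style TSV (taxa rows, sample columns).

    Duplicate taxa rows are summed. ``kingdom_map`` maps plain taxon names
    (or unrecognised k__ labels) to a kingdom when lineages do not carry one.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError("no sample columns found")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance values: {exc}") from exc
    if (df.values < 0).any():
        raise ValidationError("negative abundance value in input")
    taxa = [_parse_taxon(str(t), kingdom_map) for t in df.index]
    df.index = pd.MultiIndex.from_tuples(taxa, names=["kingdom", "rank", "name"])
    if df.index.duplicated().any():
        df = df.groupby(level=[0, 1, 2], sort=False).sum()
    if normalized is None:
        sums = df.sum(axis=0).to_numpy()
        normalized = bool(np.allclose(sums, 1.0, atol=NORM_TOL, rtol=0))
    return AbundanceTable(df, normalized=normalized)


def read_pathway_table(path, normalized: bool | None = None) -> AbundanceTable:
    """Read a pathway TSV (HUMAnN renormalized dialect): plain pathway-id
    rows, sample columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError("no sample columns found")
    df = df.astype(float)
    if (df.values < 0).any():
        raise ValidationError("negative abundance value in input")
    ids = [str(i).split("|")[-1] for i in df.index]
    ids = [i.partition("__")[2] if "__" in i else i for i in ids]
    df.index = pd.MultiIndex.from_tuples(
        [("pathway", "pathway", i) for i in ids],
        names=["kingdom", "rank", "name"],
    )
    if df.index.duplicated().any():
        df = df.groupby(level=[0, 1, 2], sort=False).sum()
    if normalized is None:
        sums = df.sum(axis=0).to_numpy()
        normalized = bool(np.allclose(sums, 1.0, atol=NORM_TOL, rtol=0))
    return AbundanceTable(df, normalized=normalized)


def read_metadata(path) -> list[SampleMeta]:
    """Read a metadata TSV with header sample_id,region,subgroup[,age,sex]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "region", "subgroup"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata must contain columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        age = float(row["age"]) if "age" in df.columns and pd.notna(row.get("age")) else None
        sex = row.get("sex") if "sex" in df.columns and pd.notna(row.get("sex")) else None
        out.append(SampleMeta(row["sample_id"], row["region"], row["subgroup"], age, sex))
    return out


def metadata_frame(meta: Iterable[SampleMeta]) -> pd.DataFrame:
    rows = [(m.sample_id, m.region, m.subgroup, m.age, m.sex) for m in meta]
    return pd.DataFrame(rows, columns=["sample_id", "region", "subgroup", "age", "sex"]).set_index("sample_id")


def renormalize(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample column to sum to 1."""
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample column(s): {list(zero.index)}")
    return AbundanceTable(table.data.div(sums, axis=1), normalized=True)


def filter_rare_taxa(table: AbundanceTable, floor: float = 1e-4,
                     statistic: str = "mean") -> AbundanceTable:
    """Drop taxa whose mean (or max) relative abundance is below ``floor``.

    The 0.01% rare-genus filter used before enterotyping corresponds to
    ``floor=1e-4`` on a normalized table. The result is renormalized so the
    surviving rows again form compositions.
    """
    if not table.normalized:
        raise ValidationError("filter_rare_taxa requires a normalized table")
    if not (0 <= floor < 1):
        raise ValueError(f"floor must be in [0, 1), got {floor}")
    if statistic == "mean":
        stat = table.data.mean(axis=1)
    elif statistic == "max":
        stat = table.data.max(axis=1)
    else:
        raise ValueError(f"statistic must be 'mean' or 'max', got {statistic!r}")
    keep = stat >= floor if floor > 0 else stat >= 0
    return renormalize(AbundanceTable(table.data.loc[keep.to_numpy()].copy()))


def filter_low_prevalence(table: AbundanceTable, min_samples: int = 10) -> AbundanceTable:
    """Drop features detected (nonzero) in fewer than ``min_samples`` samples."""
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({table.n_samples})"
        )
    present = (table.data > 0).sum(axis=1)
    keep = (present >= min_samples).to_numpy()
    out = AbundanceTable(table.data.loc[keep].copy())
    return renormalize(out) if table.normalized else out


def split_by_kingdom(table: AbundanceTable) -> dict[str, AbundanceTable]:
    """Partition rows by kingdom and renormalize within each kingdom."""
    if not table.normalized:
        raise ValidationError("split_by_kingdom requires a normalized table")
    out: dict[str, AbundanceTable] = {}
    for kingdom in table.data.index.get_level_values("kingdom").unique():
        sub = table.data.xs(kingdom, level="kingdom", drop_level=False).copy()
        sums = sub.sum(axis=0)
        if (sums == 0).any():
            # samples with no reads in this kingdom cannot form a composition
            dead = list(sums.index[sums == 0])
            raise ValidationError(f"samples with zero {kingdom} abundance: {dead}")
        out[str(kingdom)] = AbundanceTable(sub.div(sums, axis=1), normalized=True)
    return out
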