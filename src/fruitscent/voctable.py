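"""Volatile-compound tables: data model, filtering, normalisation, class aggregation.

The central object is a :class:`ScentTable`: a samples x compounds matrix of
internal-standard-normalised amounts plus per-sample metadata (species,
individual, ripeness, site).  Downstream analyses work on species-level
*relative* amounts (:class:`SpeciesProfile`, rows summing to 1), either per
compound or aggregated into seven biochemical classes defined by the
biosynthetic pathway of each volatile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical biochemical class order (fixed so outputs are byte-stable).
CLASS_ORDER: tuple[str, ...] = (
    "aliphatics",
    "aromatics",
    "C5-branched",
    "terpenoids",
    "nitrogen_sulfur",
    "misc_cyclic",
    "unknown",
)

#: Metadata columns recognised in delimited scent tables.
META_COLUMNS: tuple[str, ...] = ("sample", "species", "individual", "ripeness", "site")

RIPENESS_LEVELS = frozenset({"ripe", "unripe"})


class FilterRule:
    """Names of the compound-removal rules, used in removal logs."""

    CONTROL = "control_contaminant"
    UBIQUITY = "ubiquity"
    RARE = "rare_single_species"
    MAX_SHARE = "low_max_share"


@dataclass
class ScentTable:
    """Samples x compounds amount matrix with sample metadata.

    Parameters
    ----------
    amounts : pandas.DataFrame
        Non-negative amounts; index = sample ids, columns = compound ids.
    meta : pandas.DataFrame
        Indexed by sample id; must contain a ``species`` column, and may
        contain ``individual``, ``ripeness`` and ``site``.
    """

    amounts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.amounts = self.amounts.astype(float)
        self.amounts.index.name = "sample"
        self.meta.index.name = "sample"
        if self.amounts.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.amounts.columns.has_duplicates:
            raise ValueError("duplicate compound identifiers")
        if (self.amounts.to_numpy() < 0).any():
            raise ValueError("negative amounts in scent table")
        if "species" not in self.meta.columns:
            raise ValueError("meta must contain a 'species' column")
        missing = self.amounts.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        self.meta = self.meta.loc[self.amounts.index]
        if self.meta["species"].isna().any():
            raise ValueError("every sample needs a species label")
        if "ripeness" in self.meta.columns:
            bad = set(self.meta["ripeness"].dropna()) - RIPENESS_LEVELS
            if bad:
                raise ValueError(f"invalid ripeness levels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.amounts.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.amounts.columns)

    @property
    def species_of(self) -> pd.Series:
        return self.meta["species"]

    @property
    def ripeness_of(self) -> pd.Series:
        if "ripeness" not in self.meta.columns:
            return pd.Series(pd.NA, index=self.meta.index, name="ripeness")
        return self.meta["ripeness"]

    def subset_samples(self, keep: list[str]) -> "ScentTable":
        return ScentTable(self.amounts.loc[keep], self.meta.loc[keep])

    def subset_compounds(self, keep: list[str]) -> "ScentTable":
        return ScentTable(self.amounts[keep], self.meta)


@dataclass
class ClassMap:
    """Compound -> biochemical class mapping (seven-class scheme)."""

    class_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.class_of.values() if c not in CLASS_ORDER}
        if bad:
            raise ValueError(
                f"unknown class labels {sorted(bad)}; allowed: {list(CLASS_ORDER)}"
            )

    def __getitem__(self, compound: str) -> str:
        return self.class_of[compound]

    def require(self, compounds: list[str]) -> None:
        unmapped = [c for c in compounds if c not in self.class_of]
        if unmapped:
            raise KeyError(f"compounds without class annotation: {unmapped[:10]}")


@dataclass
class SpeciesProfile:
    """Species x feature matrix of relative amounts (rows sum to 1 or are all zero)."""

    values: pd.DataFrame  # index = species, columns = compounds or classes
    level: str = "compound"  # "compound" | "class"
    zero_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if (arr < -1e-12).any():
            raise ValueError("negative relative amounts")
        sums = arr.sum(axis=1)
        nonzero = sums > 0
        if not np.allclose(sums[nonzero], 1.0, atol=1e-9):
            raise ValueError("non-zero rows of a SpeciesProfile must sum to 1")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_compounds(
    table: ScentTable,
    control_samples: set[str] | frozenset[str] = frozenset(),
    ubiquity_threshold: float | None = 0.9,
    rare_sample_fraction: float | None = 0.25,
    max_share_threshold: float | None = 0.01,
) -> tuple[ScentTable, pd.DataFrame]:
    """Remove likely contaminants and uninformative compounds.

    Four independent rules, each optional (pass ``None`` to disable):

    1. *control contaminants* — compounds whose mean amount in control
       (empty-chamber) samples is at least their mean amount in fruit samples;
    2. *ubiquity* — compounds present (amount > 0) in more than
       ``ubiquity_threshold`` of all non-control samples, on the reasoning
       that a volatile detected in essentially every sample across species is
       more plausibly a contaminant than a genuine fruit compound;
    3. *rarity* — compounds present in exactly one species and in fewer than
       ``rare_sample_fraction`` of the dataset's samples;
    4. *max share* — compounds that never constitute more than
       ``max_share_threshold`` of a species' total emission (species means).

    Returns the filtered table (control samples dropped) and a removal log
    with columns ``compound``, ``rule``, ``statistic``.
    """
    if table.amounts.shape[1] == 0 or table.amounts.shape[0] == 0:
        raise ValueError("empty scent table")
    for name, thr in (
        ("ubiquity_threshold", ubiquity_threshold),
        ("rare_sample_fraction", rare_sample_fraction),
        ("max_share_threshold", max_share_threshold),
    ):
        if thr is not None and not (0 < thr <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")

    control_samples = set(control_samples)
    unknown_controls = control_samples - set(table.samples)
    if unknown_controls:
        raise ValueError(f"control samples not in table: {sorted(unknown_controls)}")
    fruit_ids = [s for s in table.samples if s not in control_samples]
    if not fruit_ids:
        raise ValueError("no non-control samples left")

    fruit = table.amounts.loc[fruit_ids]
    present = fruit > 0
    n_samples = len(fruit_ids)
    records: list[dict] = []

    # rule 1: predominance in controls (mean in controls >= mean in fruit)
    if control_samples:
        ctrl = table.amounts.loc[sorted(control_samples)]
        ctrl_mean = ctrl.mean(axis=0)
        fruit_mean = fruit.mean(axis=0)
        for c in table.compound_ids:
            if ctrl_mean[c] > 0 and ctrl_mean[c] >= fruit_mean[c]:
                records.append(
                    {"compound": c, "rule": FilterRule.CONTROL,
                     "statistic": float(ctrl_mean[c])}
                )

    # rule 2: ubiquity across all non-control samples
    if ubiquity_threshold is not None:
        prevalence = present.sum(axis=0) / n_samples
        for c in table.compound_ids:
            if prevalence[c] > ubiquity_threshold:
                records.append(
                    {"compound": c, "rule": FilterRule.UBIQUITY,
                     "statistic": float(prevalence[c])}
                )

    # rule 3: single-species rarities
    if rare_sample_fraction is not None:
        species = table.species_of.loc[fruit_ids]
        n_species_with = present.groupby(species, observed=True).any().sum(axis=0)
        prevalence = present.sum(axis=0) / n_samples
        for c in table.compound_ids:
            if n_species_with[c] == 1 and prevalence[c] < rare_sample_fraction:
                records.append(
                    {"compound": c, "rule": FilterRule.RARE,
                     "statistic": float(prevalence[c])}
                )

    # rule 4: never exceeding a minimal share of any species' emission
    if max_share_threshold is not None:
        means = species_means(ScentTable(fruit, table.meta.loc[fruit_ids]))
        totals = means.sum(axis=1)
        shares = means.divide(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
        max_share = shares.max(axis=0)
        for c in table.compound_ids:
            if max_share[c] <= max_share_threshold:
                records.append(
                    {"compound": c, "rule": FilterRule.MAX_SHARE,
                     "statistic": float(max_share[c])}
                )

    log = pd.DataFrame(records, columns=["compound", "rule", "statistic"])
    removed = set(log["compound"])
    keep = [c for c in table.compound_ids if c not in removed]
    filtered = ScentTable(fruit[keep], table.meta.loc[fruit_ids])
    return filtered, log


# ---------------------------------------------------------------------------
# normalisation and aggregation
# ---------------------------------------------------------------------------

def species_means(table: ScentTable) -> pd.DataFrame:
    """Mean amount of each compound per species (absences count as zero).

    Rows are sorted by species name so results do not depend on sample order.
    """
    means = table.amounts.groupby(table.species_of, observed=True).mean()
    means.index.name = "species"
    return means.sort_index()


def relative_amounts(matrix: pd.DataFrame, level: str = "compound") -> SpeciesProfile:
    """Divide each species row by its total emission.

    All-zero rows are left as zeros and recorded in ``zero_rows`` (with a
    warning): a species from which no volatile was detected carries no
    compositional information but should not crash a pipeline.
    """
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative amounts")
    totals = arr.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"all-zero species rows kept as zeros: {list(matrix.index[zero])}",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    rel = pd.DataFrame(arr / safe[:, None], index=matrix.index, columns=matrix.columns)
    return SpeciesProfile(rel, level=level, zero_rows=list(matrix.index[zero]))


def aggregate_classes(profile: SpeciesProfile, classmap: ClassMap) -> SpeciesProfile:
    """Sum compound-level relative amounts into the seven biochemical classes.

    Row sums are preserved exactly; output columns follow :data:`CLASS_ORDER`
    restricted to classes actually present in the mapping of these compounds.
    """
    if profile.level != "compound":
        raise ValueError("aggregate_classes expects a compound-level profile")
    classmap.require(profile.features)
    classes = pd.Series(
        [classmap[c] for c in profile.features], index=profile.values.columns
    )
    agg = profile.values.T.groupby(classes, observed=True).sum().T
    cols = [c for c in CLASS_ORDER if c in agg.columns]
    agg = agg[cols]
    return SpeciesProfile(agg, level="class", zero_rows=list(profile.zero_rows))


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","

def read_scent_table(path: str | Path, sep: str | None = None) -> ScentTable:
    """Read a wide delimited scent table.

    Layout: one ``sample`` column, optional ``species``/``individual``/
    ``ripeness``/``site`` metadata columns, every remaining column a compound.
    Empty cells are read as 0 (absence), matching occurrence-style supplements.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    if "sample" not in df.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    df = df.set_index("sample")
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols]
    amounts = df.drop(columns=meta_cols).fillna(0.0)
    return ScentTable(amounts, meta)


def write_scent_table(table: ScentTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    out = pd.concat([table.meta, table.amounts], axis=1)
    out.index.name = "sample"
    out.to_csv(path, sep=sep or _sep_for(path))


def read_class_map(path: str | Path, sep: str | None = None) -> ClassMap:
    """Read a two-column (compound, class) delimited file."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    if not {"compound", "class"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'compound' and 'class'")
    return ClassMap(dict(zip(df["compound"].astype(str), df["class"].astype(str))))


def write_class_map(classmap: ClassMap, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        sorted(classmap.class_of.items()), columns=["compound", "class"]
    )
    df.to_csv(path, sep=sep or _sep_for(path), index=False)


def write_removal_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)
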