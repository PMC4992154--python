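"""Dataset schema, validated I/O and summaries.

The analysis operates on two tables:

* an **island table** — one row per island: abiotic covariates (area in km²,
  maximum elevation in m, total annual precipitation in mm, mean annual
  temperature in °C, temperature seasonality), permanent human presence (0/1),
  presence/absence of 12 broad invasive-mammal groups, and per-group
  eradication flags (1 where the group was present historically but has since
  been removed);
* a **population table** — one row per native species-on-island record: the
  species, its island, a six-level class/volancy category, optional body mass,
  and the binary outcome (1 = the population was extirpated after AD 1500,
  0 = it persists).

Islands are the cluster unit of the regression; populations are the
observation unit.  Invasive presence is recorded *historically* (eradicated
groups count as present) because that is the exposure that shaped observed
extirpations; ``current_presence`` applies the eradication flags for
prediction under present-day conditions.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical invasive-mammal group names (island-table columns).
INVASIVE_GROUPS: tuple[str, ...] = (
    "canids",
    "felids",
    "mustelids_mongooses",
    "pigs",
    "primates",
    "medium_omnivores",
    "small_omnivores",
    "rats",
    "mice",
    "large_herbivores",
    "medium_herbivores",
    "lagomorphs",
)

#: Six native-species categories combining taxonomic class and flight ability.
CLASS_VOLANCY_LEVELS: tuple[str, ...] = (
    "amphibian",
    "bat",
    "nonvolant_bird",
    "nonvolant_mammal",
    "reptile",
    "volant_bird",
)

ISLAND_REQUIRED = (
    "island_id",
    "area",
    "elevation",
    "precipitation",
    "mean_temperature",
    "temperature_seasonality",
    "human_presence",
)
POPULATION_REQUIRED = ("species_id", "island_id", "class_volancy", "extirpated")
POPULATION_OPTIONAL = ("body_mass", "extant", "single_island_endemic")


class SchemaError(ValueError):
    """A table does not match the documented column schema."""


class IntegrityError(ValueError):
    """Cross-table referential integrity or per-row invariants violated."""


@dataclasses.dataclass
class Dataset:
    """Validated island + population tables.

    ``islands`` is indexed 0..n-1 with an ``island_id`` column;
    ``populations`` likewise with ``species_id``/``island_id``.  ``provenance``
    is free-text metadata (source, generator parameters, ...).
    """

    islands: pd.DataFrame
    populations: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        isl, pop = self.islands, self.populations
        for col in ISLAND_REQUIRED:
            if col not in isl.columns:
                raise SchemaError(f"island table missing required column {col!r}")
        for col in POPULATION_REQUIRED:
            if col not in pop.columns:
                raise SchemaError(f"population table missing required column {col!r}")
        if isl["island_id"].duplicated().any():
            dups = isl.loc[isl["island_id"].duplicated(), "island_id"].tolist()
            raise IntegrityError(f"duplicate island_id values: {dups}")
        if len(isl) and (isl["area"] <= 0).any():
            bad = isl.loc[isl["area"] <= 0, "island_id"].tolist()
            raise IntegrityError(f"non-positive area for islands: {bad}")
        if len(isl) and (isl["precipitation"] < 0).any():
            bad = isl.loc[isl["precipitation"] < 0, "island_id"].tolist()
            raise IntegrityError(f"negative precipitation for islands: {bad}")
        for g in INVASIVE_GROUPS:
            if g not in isl.columns:
                raise SchemaError(f"island table missing invasive-group column {g!r}")
            _check_binary(isl[g], g)
            ecol = f"eradicated_{g}"
            if ecol in isl.columns:
                _check_binary(isl[ecol], ecol)
                orphan = (isl[ecol] == 1) & (isl[g] == 0)
                if orphan.any():
                    bad = isl.loc[orphan, "island_id"].tolist()
                    raise IntegrityError(
                        f"eradication flag without historical presence for {g}: {bad}"
                    )
        _check_binary(isl["human_presence"], "human_presence")
        _check_binary(pop["extirpated"], "extirpated")

        unknown = set(pop["island_id"]) - set(isl["island_id"])
        if unknown:
            raise IntegrityError(
                f"population rows reference unknown islands: {sorted(map(str, unknown))}"
            )
        key = pop[["species_id", "island_id"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_records(index=False).tolist()
            raise IntegrityError(f"duplicate (species_id, island_id) pairs: {dups}")
        bad_levels = set(pop["class_volancy"]) - set(CLASS_VOLANCY_LEVELS)
        if bad_levels:
            raise SchemaError(f"unknown class_volancy levels: {sorted(bad_levels)}")
        if "extant" in pop.columns:
            if ((pop["extant"].astype(int) + pop["extirpated"].astype(int)) != 1).any():
                raise IntegrityError("extant must equal 1 - extirpated for every row")

    # -- convenience accessors -------------------------------------------------

    def historical_presence(self, group: str) -> pd.Series:
        """Presence used for model fitting (eradicated groups count as present)."""
        if group not in INVASIVE_GROUPS:
            raise KeyError(f"unknown invasive group {group!r}")
        return self.islands[group].astype(int)

    def current_presence(self, group: str) -> pd.Series:
        """Present-day presence: historical presence with eradications applied."""
        pres = self.historical_presence(group)
        ecol = f"eradicated_{group}"
        if ecol in self.islands.columns:
            pres = pres * (1 - self.islands[ecol].astype(int))
        return pres

    def copy(self) -> "Dataset":
        return Dataset(
            self.islands.copy(), self.populations.copy(), self.provenance
        )


def _check_binary(s: pd.Series, name: str) -> None:
    vals = set(pd.unique(s.dropna()))
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError(f"column {name!r} must be binary 0/1, got values {sorted(map(str, vals))}")


def _normalize_headers(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    df = df.rename(columns=lambda c: str(c).strip().lower())
    if column_map:
        df = df.rename(columns={str(k).lower(): v for k, v in column_map.items()})
    return df


def read_dataset(
    island_path: str | Path,
    population_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Read and validate the island and population CSV tables.

    Headers are matched case-insensitively; ``column_map`` renames
    non-standard headers to canonical ones.  Blank cells in invasive-group
    (and eradication) columns are coded 0: absence of information about an
    invasive mammal is treated as absence of the mammal.  Unknown columns in
    the island table are rejected so that misspelled invasive groups cannot
    silently drop out of the analysis.
    """
    isl = _normalize_headers(pd.read_csv(island_path, thousands=None), column_map)
    pop = _normalize_headers(pd.read_csv(population_path, thousands=None), column_map)

    known = set(ISLAND_REQUIRED) | set(INVASIVE_GROUPS) | {
        f"eradicated_{g}" for g in INVASIVE_GROUPS
    }
    unknown = [c for c in isl.columns if c not in known]
    if unknown:
        raise SchemaError(
            f"unrecognized island-table columns {unknown}; "
            f"invasive groups must be among {sorted(INVASIVE_GROUPS)}"
        )
    for g in INVASIVE_GROUPS:
        if g in isl.columns:
            isl[g] = isl[g].fillna(0).astype(int)  # no information -> absent
        else:
            isl[g] = 0
        ecol = f"eradicated_{g}"
        if ecol in isl.columns:
            isl[ecol] = isl[ecol].fillna(0).astype(int)
    isl["human_presence"] = isl["human_presence"].fillna(0).astype(int)

    keep = [c for c in pop.columns if c in POPULATION_REQUIRED + POPULATION_OPTIONAL]
    missing = [c for c in POPULATION_REQUIRED if c not in keep]
    if missing:
        raise SchemaError(f"population table missing required columns {missing}")
    pop = pop[keep]
    if not set(pd.unique(pop["extirpated"].dropna())) <= {0, 1, 0.0, 1.0}:
        raise ValueError("population outcome column 'extirpated' must be binary 0/1")
    pop["extirpated"] = pop["extirpated"].astype(int)
    if "extant" not in pop.columns:
        pop["extant"] = 1 - pop["extirpated"]
    if "single_island_endemic" not in pop.columns:
        pop["single_island_endemic"] = (
            pop.groupby("species_id")["island_id"].transform("nunique") == 1
        ).astype(int)

    return Dataset(
        islands=isl.reset_index(drop=True),
        populations=pop.reset_index(drop=True),
        provenance=f"read from {island_path} + {population_path}",
    )


def summarize_dataset(ds: Dataset) -> dict:
    """Headline descriptive statistics of a dataset.

    Mirrors the descriptive quantities reported for the global study: record
    counts, extirpation prevalence, fraction of islands carrying at least one
    invasive group, and median area/precipitation stratified by human
    presence.  An empty dataset yields zero counts and NaN medians.
    """
    isl, pop = ds.islands, ds.populations
    n_isl, n_pop = len(isl), len(pop)
    out: dict = {
        "n_islands": n_isl,
        "n_populations": n_pop,
        "n_species": int(pop["species_id"].nunique()) if n_pop else 0,
        "n_extirpated": int(pop["extirpated"].sum()) if n_pop else 0,
    }
    out["extirpation_fraction"] = out["n_extirpated"] / n_pop if n_pop else float("nan")
    if n_isl:
        inv = isl[list(INVASIVE_GROUPS)].to_numpy()
        out["frac_islands_invaded"] = float((inv.sum(axis=1) > 0).mean())
        uninhab = isl["human_presence"] == 0
        out["frac_islands_uninhabited"] = float(uninhab.mean())
        for label, mask in (
            ("all", np.ones(n_isl, bool)),
            ("uninhabited", uninhab.to_numpy()),
            ("inhabited", (~uninhab).to_numpy()),
        ):
            sub = isl.loc[mask]
            out[f"median_area_{label}"] = float(sub["area"].median()) if len(sub) else float("nan")
            out[f"median_precip_{label}"] = (
                float(sub["precipitation"].median()) if len(sub) else float("nan")
            )
    else:
        out["frac_islands_invaded"] = float("nan")
        out["frac_islands_uninhabited"] = float("nan")
        for label in ("all", "uninhabited", "inhabited"):
            out[f"median_area_{label}"] = float("nan")
            out[f"median_precip_{label}"] = float("nan")
    return out


def write_table(rows, path: str | Path) -> None:
    """Write a tabular result as UTF-8 CSV with header, deterministic order."""
    if rows is None:
        raise ValueError("rows must not be None")
    if isinstance(rows, dict):
        rows = pd.DataFrame([rows])
    elif not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    buf = io.StringIO()
    rows.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_dataset(ds: Dataset, island_path: str | Path, population_path: str | Path) -> None:
    """Write a dataset back to the two-table CSV form (round-trips via read)."""
    write_table(ds.islands, island_path)
    write_table(ds.populations, population_path)
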