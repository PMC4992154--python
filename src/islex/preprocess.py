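"""Covariate transforms, screening, ordination diagnostics and design matrices.

Continuous covariates with skewed distributions enter the model on the
natural-log scale (area, temperature seasonality); island elevation is
replaced by the residual of ln(elevation+1) regressed on ln(area), because
area and elevation are strongly collinear and the residual captures
topographic complexity independent of size.  Precipitation stays in raw mm.

The design matrix encodes the six-level class/volancy factor as dummies
against a reference level, interactions as elementwise products, and carries
the island id of every row so the estimating equations can group by cluster.
Rows are sorted by (island_id, species_id) so the ordering is stable and
cluster-contiguous.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .datamodel import CLASS_VOLANCY_LEVELS, INVASIVE_GROUPS, Dataset

logger = logging.getLogger(__name__)

#: Continuous / ordinal covariates entered in the pairwise correlation screen.
SCREEN_CONTINUOUS = (
    "ln_area",
    "ln_elevation",
    "precipitation",
    "mean_temperature",
    "ln_seasonality",
    "human_presence",
)


class SpecificationError(ValueError):
    """A model specification references unavailable or excluded terms."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Declarative model formula: main effects plus pairwise interactions.

    ``class_volancy`` is a single term that expands to five dummy columns
    against ``reference_level``; every other term is a single numeric column
    of the (transformed) island table or an invasive-group presence flag.
    """

    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    reference_level: str = "amphibian"

    def __post_init__(self):
        if len(set(self.main_effects)) != len(self.main_effects):
            raise SpecificationError("duplicate main effects in model spec")
        if len(set(self.interactions)) != len(self.interactions):
            raise SpecificationError("duplicate interactions in model spec")
        for a, b in self.interactions:
            for t in (a, b):
                if t not in self.main_effects:
                    raise SpecificationError(
                        f"interaction component {t!r} missing from main effects"
                    )
        if self.reference_level not in CLASS_VOLANCY_LEVELS:
            raise SpecificationError(
                f"unknown reference level {self.reference_level!r}"
            )

    def with_terms(
        self,
        mains: Iterable[str] = (),
        interactions: Iterable[tuple[str, str]] = (),
    ) -> "ModelSpec":
        """A new spec with extra terms appended (mains added as needed)."""
        new_mains = list(self.main_effects)
        new_inter = list(self.interactions)
        for m in mains:
            if m not in new_mains:
                new_mains.append(m)
        for a, b in interactions:
            for t in (a, b):
                if t not in new_mains:
                    new_mains.append(t)
            if (a, b) not in new_inter:
                new_inter.append((a, b))
        return ModelSpec(tuple(new_mains), tuple(new_inter), self.reference_level)

    def to_dict(self) -> dict:
        return {
            "main_effects": list(self.main_effects),
            "interactions": [list(p) for p in self.interactions],
            "reference_level": self.reference_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            tuple(d["main_effects"]),
            tuple(tuple(p) for p in d.get("interactions", ())),
            d.get("reference_level", "amphibian"),
        )


#: The final global model: eight main effects and five interactions.
FINAL_MODEL_SPEC = ModelSpec(
    main_effects=(
        "class_volancy",
        "ln_area",
        "precipitation",
        "human_presence",
        "felids",
        "rats",
        "pigs",
        "mustelids_mongooses",
    ),
    interactions=(
        ("class_volancy", "ln_area"),
        ("class_volancy", "precipitation"),
        ("class_volancy", "felids"),
        ("class_volancy", "pigs"),
        ("rats", "ln_area"),
    ),
)


@dataclasses.dataclass
class DesignMatrix:
    """Numeric encoding of a model spec over a dataset.

    Rows are sorted by (island_id, species_id) and therefore contiguous by
    cluster; ``cluster_index`` holds the island id of each row.
    """

    y: np.ndarray
    X: pd.DataFrame
    cluster_index: np.ndarray
    term_map: dict[str, str]
    spec: ModelSpec
    n_dropped: int = 0
    row_index: pd.DataFrame | None = None  # (species_id, island_id) per row

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def cluster_starts(self) -> np.ndarray:
        """Start offsets of each cluster block (rows are cluster-contiguous)."""
        change = np.r_[True, self.cluster_index[1:] != self.cluster_index[:-1]]
        return np.flatnonzero(change)

    def subset_rows(self, mask: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            y=self.y[mask],
            X=self.X.loc[mask].reset_index(drop=True),
            cluster_index=self.cluster_index[mask],
            term_map=self.term_map,
            spec=self.spec,
            n_dropped=self.n_dropped,
            row_index=None
            if self.row_index is None
            else self.row_index.loc[mask].reset_index(drop=True),
        )


def transform_covariates(islands: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns: ln_area, ln_elevation, ln_seasonality, elevation_residual.

    ``elevation_residual`` is the OLS residual of ln(elevation+1) on ln(area);
    the +1 offset accommodates zero-elevation atolls.  Residuals have mean
    exactly 0 by the normal equations.
    """
    if (islands["area"] <= 0).any():
        bad = islands.loc[islands["area"] <= 0, "island_id"].tolist()
        raise ValueError(f"non-positive area for islands {bad}; cannot log-transform")
    if (islands["temperature_seasonality"] <= 0).any():
        bad = islands.loc[
            islands["temperature_seasonality"] <= 0, "island_id"
        ].tolist()
        raise ValueError(f"non-positive temperature seasonality for islands {bad}")
    out = islands.copy()
    out["ln_area"] = np.log(out["area"].to_numpy(float))
    out["ln_elevation"] = np.log1p(out["elevation"].to_numpy(float))
    out["ln_seasonality"] = np.log(out["temperature_seasonality"].to_numpy(float))
    x = out["ln_area"].to_numpy()
    z = out["ln_elevation"].to_numpy()
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    out["elevation_residual"] = z - A @ coef
    return out


@dataclasses.dataclass
class ScreeningReport:
    """Outcome of the covariate screen prior to model selection."""

    correlations: pd.DataFrame  # all continuous pairs with Pearson r
    flagged_pairs: list[tuple[str, str, float]]  # |r| > threshold
    group_prevalence: pd.Series  # fraction of islands occupied, per group
    excluded_rare_groups: list[str]  # prevalence < threshold
    excluded_missing: list[str]  # covariates over the missingness ceiling
    candidate_terms: list[str]  # surviving main-effect candidates


def covariate_screen(
    ds: Dataset,
    r_threshold: float = 0.7,
    prevalence_threshold: float = 0.10,
    max_missing_fraction: float = 0.25,
) -> ScreeningReport:
    """Screen covariates before model selection.

    Flags continuous pairs with |Pearson r| above ``r_threshold`` (area and
    elevation being the canonical offender, resolved by the area–elevation
    residual), excludes invasive groups occupying fewer than
    ``prevalence_threshold`` of islands, and excludes population covariates
    (body mass) whose missingness exceeds ``max_missing_fraction``.
    Constant columns yield an undefined (NaN) correlation, not an error.
    """
    isl = transform_covariates(ds.islands)
    rows = []
    flagged: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(SCREEN_CONTINUOUS, 2):
        xa, xb = isl[a].to_numpy(float), isl[b].to_numpy(float)
        if np.std(xa) == 0 or np.std(xb) == 0 or len(xa) < 2:
            r = float("nan")
        else:
            r = float(pearsonr(xa, xb)[0])
        rows.append({"var_a": a, "var_b": b, "r": r})
        if np.isfinite(r) and abs(r) > r_threshold:
            flagged.append((a, b, r))

    prevalence = isl[list(INVASIVE_GROUPS)].mean()
    rare = sorted(prevalence.index[prevalence < prevalence_threshold])

    excluded_missing = []
    pop = ds.populations
    if "body_mass" in pop.columns:
        if pop["body_mass"].isna().mean() > max_missing_fraction:
            excluded_missing.append("body_mass")

    flagged_names = {n for a, b, _ in flagged for n in (a, b)}
    candidates = ["class_volancy"]
    for name in ("ln_area", "precipitation", "mean_temperature", "ln_seasonality",
                 "elevation_residual", "human_presence"):
        candidates.append(name)
    # elevation enters only via the residual; drop raw elevation if correlated
    candidates = [c for c in candidates if c != "ln_elevation"]
    candidates += [g for g in INVASIVE_GROUPS if g not in rare]
    _ = flagged_names  # reported; the residual substitution already resolves area-elevation

    return ScreeningReport(
        correlations=pd.DataFrame(rows),
        flagged_pairs=flagged,
        group_prevalence=prevalence,
        excluded_rare_groups=rare,
        excluded_missing=excluded_missing,
        candidate_terms=candidates,
    )


def cooccurrence_ordination(
    islands: pd.DataFrame,
    groups: Sequence[str] = INVASIVE_GROUPS,
    n_iter: int = 300,
    tol: float = 1e-9,
) -> tuple[pd.DataFrame, float]:
    """2-D ordination of invasive groups by co-occurrence across islands.

    Groups (variables) are the points; the dissimilarity between two groups is
    the Euclidean distance between their presence/absence vectors over all
    islands.  The embedding starts from classical (Torgerson) MDS and is
    refined by SMACOF stress majorization; returns the configuration and the
    final Kruskal stress-1.  A diagnostic: strongly co-occurring groups land
    close together, flagging candidates for merging.
    """
    if len(groups) < 3:
        raise ValueError("ordination needs at least 3 invasive groups")
    M = islands[list(groups)].to_numpy(float).T  # groups x islands
    D = squareform(pdist(M, metric="euclidean"))
    n = len(groups)

    # classical MDS initialization
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    X = V[:, order] * np.sqrt(np.maximum(w[order], 0))
    if X.shape[1] < 2:  # degenerate rank
        X = np.column_stack([X, np.zeros(n)])

    def _dists(X):
        return squareform(pdist(X))

    def _raw_stress(X):
        return float(np.sum((_dists(X) - D) ** 2) / 2)

    prev = _raw_stress(X)
    for _ in range(n_iter):
        d = _dists(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, D / d, 0.0)
        Bmat = -ratio
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1) + np.diag(Bmat))
        X = (Bmat @ X) / n  # Guttman transform (unit weights)
        cur = _raw_stress(X)
        if prev - cur < tol * max(prev, 1.0):
            prev = cur
            break
        prev = cur

    d = _dists(X)
    denom = float(np.sum(d**2) / 2)
    stress1 = float(np.sqrt(prev / denom)) if denom > 0 else 0.0
    emb = pd.DataFrame(X, index=list(groups), columns=["dim1", "dim2"])
    return emb, stress1


def _main_columns(
    base: pd.DataFrame, term: str, reference_level: str
) -> dict[str, np.ndarray]:
    """Encoded column(s) for one main-effect term."""
    if term == "class_volancy":
        return {
            f"class_volancy[{lev}]": (base["class_volancy"] == lev).to_numpy(float)
            for lev in CLASS_VOLANCY_LEVELS
            if lev != reference_level
        }
    if term not in base.columns:
        raise SpecificationError(f"term {term!r} not available in the data")
    return {term: base[term].to_numpy(float)}


def encode_base(base: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Encode a base covariate table (one row per observation) per the spec.

    Returns the named numeric matrix (with intercept) and a column→term map.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(base))}
    term_map: dict[str, str] = {"intercept": "intercept"}
    for term in spec.main_effects:
        for name, col in _main_columns(base, term, spec.reference_level).items():
            cols[name] = col
            term_map[name] = term
    for a, b in spec.interactions:
        for na, ca in _main_columns(base, a, spec.reference_level).items():
            for nb, cb in _main_columns(base, b, spec.reference_level).items():
                name = f"{na}:{nb}"
                cols[name] = ca * cb
                term_map[name] = f"{a}:{b}"
    X = pd.DataFrame(cols, index=base.index)
    return X, term_map


def spec_from_term_map(term_map: Mapping[str, str], reference_level: str = "amphibian") -> ModelSpec:
    """Reconstruct the ModelSpec from a design's column→term bookkeeping."""
    mains: list[str] = []
    inters: list[tuple[str, str]] = []
    for term in term_map.values():
        if term == "intercept":
            continue
        if ":" in term:
            pair = tuple(term.split(":"))
            if pair not in inters:
                inters.append(pair)  # type: ignore[arg-type]
        elif term not in mains:
            mains.append(term)
    return ModelSpec(tuple(mains), tuple(inters), reference_level)


def build_design(
    ds: Dataset,
    spec: ModelSpec,
    use_historical_presence: bool = True,
) -> DesignMatrix:
    """Assemble the numeric design matrix with cluster index.

    Invasive-presence terms use historical presence (eradicated groups count
    as present) when ``use_historical_presence`` is set — the exposure under
    which observed extirpations accrued — and current presence (eradications
    applied) otherwise, for present-day prediction.  Rows with any missing
    required covariate are dropped with a logged count.
    """
    isl = transform_covariates(ds.islands).copy()
    for g in INVASIVE_GROUPS:
        isl[g] = (
            ds.historical_presence(g) if use_historical_presence else ds.current_presence(g)
        ).to_numpy()
    merged = ds.populations.merge(isl, on="island_id", how="left", validate="m:1")
    merged = merged.sort_values(["island_id", "species_id"], kind="mergesort").reset_index(
        drop=True
    )

    needed = set()
    for term in spec.main_effects:
        needed.add(term)
    needed.discard("class_volancy")
    base_cols = ["class_volancy"] + sorted(needed)
    for c in base_cols:
        if c not in merged.columns:
            raise SpecificationError(f"term {c!r} not available in the data")
    ok = merged[base_cols].notna().all(axis=1) & merged["extirpated"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing covariates", n_dropped)
    merged = merged.loc[ok].reset_index(drop=True)

    X, term_map = encode_base(merged, spec)
    return DesignMatrix(
        y=merged["extirpated"].to_numpy(int),
        X=X,
        cluster_index=merged["island_id"].to_numpy(),
        term_map=term_map,
        spec=spec,
        n_dropped=n_dropped,
        row_index=merged[["species_id", "island_id"]].copy(),
    )


def encode_profiles(profiles: pd.DataFrame, spec: ModelSpec, columns: Sequence[str]) -> pd.DataFrame:
    """Encode covariate profiles (rows of raw covariate settings) to design columns.

    Used for odds-ratio and risk-profile evaluation: each profile supplies
    ``class_volancy`` plus every numeric/binary main effect of the spec.
    """
    X, _ = encode_base(profiles.reset_index(drop=True), spec)
    missing = [c for c in columns if c not in X.columns]
    if missing:
        raise SpecificationError(f"profiles do not produce design columns {missing}")
    return X[list(columns)]
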