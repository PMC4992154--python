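"""Cluster-level cross-validation, ROC/AUC and influence diagnostics.

Validation respects the clustering: whole islands are assigned to folds, so
no island ever contributes rows to both the training and the test side of a
split.  Each of the K test folds in each repeat is one validation run; runs
report four prediction-error statistics (mean error, mean absolute error, SD
of error, MSE) plus the AUC of the held-out rows.

AUC uses the Mann–Whitney rank formulation with ties counted one half —
exactly the proportion of concordant (positive, negative) score pairs — in
O(n log n).  Influence diagnostics refit the model exactly with each island
deleted and summarize the coefficient displacement with a Cook-type
quadratic form in the robust covariance.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import Dataset
from .gee import GEEFit, fit_gee, predict_probability
from .preprocess import DesignMatrix, ModelSpec, build_design

logger = logging.getLogger(__name__)


def kfold_partition(cluster_ids, k: int, seed) -> pd.Series:
    """Randomly assign clusters to K folds of near-equal size.

    A pure function of (cluster set, k, seed): cluster ids are sorted before
    shuffling, so row order of the input is irrelevant.  Fold sizes differ by
    at most one.
    """
    clusters = np.unique(np.asarray(cluster_ids))
    if k > len(clusters):
        raise ValueError(f"k={k} exceeds the number of clusters ({len(clusters)})")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(clusters))
    fold = np.empty(len(clusters), int)
    for f, chunk in enumerate(np.array_split(np.arange(len(clusters)), k)):
        fold[perm[chunk]] = f
    return pd.Series(fold, index=clusters, name="fold")


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC (ties counted ½) and the full ROC step curve.

    Equals the probability that a randomly chosen extirpated record scores
    above a randomly chosen persisting one.  Invariant under strictly
    monotone transforms of the scores.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present to compute AUC")
    r = rankdata(s)
    auc = (float(r[y == 1].sum()) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    last = np.r_[np.flatnonzero(np.diff(ss) != 0), len(ss) - 1]  # threshold blocks
    curve = pd.DataFrame(
        {
            "threshold": ss[last],
            "tpr": tp[last] / n_pos,
            "fpr": fp[last] / n_neg,
        }
    )
    curve = pd.concat(
        [pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}), curve],
        ignore_index=True,
    )
    return float(auc), curve


@dataclasses.dataclass
class ErrorStats:
    """The four prediction-error statistics of a validation run."""

    mean_error: float
    mean_abs_error: float
    sd_error: float
    mse: float


def error_stats(observed, predicted) -> ErrorStats:
    """Errors e = observed − predicted; SD uses the n−1 denominator."""
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    e = o - p
    return ErrorStats(
        mean_error=float(e.mean()),
        mean_abs_error=float(np.abs(e).mean()),
        sd_error=float(e.std(ddof=1)) if len(e) > 1 else 0.0,
        mse=float((e**2).mean()),
    )


def cross_validate(
    ds: Dataset,
    spec: ModelSpec,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    use_historical_presence: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Repeated K-fold cross-validation at the island (cluster) level.

    For every repeat the islands are re-partitioned into K folds; for every
    fold a fresh model is fitted on the remaining islands and scored on the
    held-out rows, yielding K·repeats validation runs.  Runs whose test fold
    contains a single outcome class get a missing AUC and are excluded from
    the AUC aggregates (their count is reported).
    """
    dm = build_design(ds, spec, use_historical_presence=use_historical_presence)
    full_fit = fit_gee(dm, warn=False)  # warm start for fold refits
    ss = np.random.SeedSequence(seed)
    rows = []
    n_single_class = 0
    n_failed = 0
    for rep, child in enumerate(ss.spawn(repeats)):
        rng = np.random.default_rng(child)
        folds = kfold_partition(dm.cluster_index, k, rng)
        row_fold = folds.loc[dm.cluster_index].to_numpy()
        for f in range(k):
            test = row_fold == f
            train = ~test
            assert not np.intersect1d(
                np.unique(dm.cluster_index[train]), np.unique(dm.cluster_index[test])
            ).size, "cluster straddles train and test"
            try:
                fit = fit_gee(
                    dm.subset_rows(train),
                    start_params=full_fit.params.to_numpy(),
                    warn=False,
                )
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            pred = predict_probability(fit, dm.subset_rows(test))
            obs = dm.y[test]
            es = error_stats(obs, pred)
            if len(np.unique(obs)) < 2:
                auc = np.nan
                n_single_class += 1
            else:
                auc, _ = roc_auc(pred, obs)
            rows.append(
                {
                    "repeat_id": rep,
                    "fold_id": f,
                    "auc": auc,
                    "mean_error": es.mean_error,
                    "mean_abs_error": es.mean_abs_error,
                    "sd_error": es.sd_error,
                    "mse": es.mse,
                    "n_test_rows": int(test.sum()),
                    "converged": fit.converged,
                }
            )
    runs = pd.DataFrame(rows)
    auc_used = runs["auc"].dropna()
    aggregates = {
        "n_runs": len(runs),
        "n_runs_auc": int(len(auc_used)),
        "n_single_class_folds": n_single_class,
        "n_failed_fits": n_failed,
        "mean_auc": float(auc_used.mean()) if len(auc_used) else float("nan"),
        "sd_auc": float(auc_used.std(ddof=1)) if len(auc_used) > 1 else float("nan"),
        "se_auc": float(auc_used.std(ddof=1) / np.sqrt(len(auc_used)))
        if len(auc_used) > 1
        else float("nan"),
        "mean_error": float(runs["mean_error"].mean()),
        "mean_abs_error": float(runs["mean_abs_error"].mean()),
        "sd_error": float(runs["sd_error"].mean()),
        "mse": float(runs["mse"].mean()),
    }
    return runs, aggregates


def cluster_influence(
    dm: DesignMatrix,
    fit: GEEFit | None = None,
    n_detail_clusters: int = 3,
) -> pd.DataFrame:
    """Leave-one-island-out deletion diagnostics by exact refitting.

    For every island, the model is refitted without it (warm-started at the
    full-data solution) and the coefficient displacement Δβ is summarized by
    the Cook-type statistic Δβᵀ Σ_robust⁻¹ Δβ.  Returns one row per island,
    sorted by influence; within the ``n_detail_clusters`` most influential
    islands, observation-level refits are summarized in ``max_obs_cook``.
    """
    if fit is None:
        fit = fit_gee(dm, warn=False)
    beta0 = fit.params.to_numpy()
    cov_inv = np.linalg.pinv(fit.robust_cov.to_numpy())
    clusters = pd.unique(dm.cluster_index)
    rows = []
    deltas = {}
    for cid in clusters:
        mask = dm.cluster_index != cid
        try:
            f = fit_gee(dm.subset_rows(mask), start_params=beta0, warn=False)
            db = f.params.to_numpy() - beta0
            cook = float(db @ cov_inv @ db)
            flagged = not f.converged
        except np.linalg.LinAlgError:
            db = np.full_like(beta0, np.nan)
            cook = np.nan
            flagged = True
        deltas[cid] = db
        rows.append(
            {
                "island_id": cid,
                "cook": cook,
                "max_abs_delta": float(np.nanmax(np.abs(db))),
                "n_rows": int((~mask).sum()),
                "flagged": flagged,
            }
        )
    out = pd.DataFrame(rows).sort_values("cook", ascending=False).reset_index(drop=True)

    detail = {}
    for cid in out["island_id"].head(n_detail_clusters):
        idx = np.flatnonzero(dm.cluster_index == cid)
        worst = 0.0
        for j in idx:
            mask = np.ones(dm.n_obs, bool)
            mask[j] = False
            try:
                f = fit_gee(dm.subset_rows(mask), start_params=beta0, warn=False)
                db = f.params.to_numpy() - beta0
                worst = max(worst, float(db @ cov_inv @ db))
            except np.linalg.LinAlgError:
                worst = np.nan
                break
        detail[cid] = worst
    out["max_obs_cook"] = out["island_id"].map(detail)

    delta_cols = pd.DataFrame(
        [deltas[c] for c in out["island_id"]], columns=[f"d_{c}" for c in fit.columns]
    )
    return pd.concat([out, delta_cols], axis=1)
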