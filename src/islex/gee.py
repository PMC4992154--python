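"""Generalized estimating equations for clustered binary outcomes.

Fits the marginal model g(p_ij) = x_ijᵀβ with the complementary log-log link
g(p) = ln(−ln(1−p)) — appropriate when the binary response is dominated by
zeros — and an exchangeable working correlation within clusters (islands).
Estimation solves Σ_i D_iᵀ V_i⁻¹ (y_i − μ_i) = 0 by Fisher-scoring style
updates, re-estimating the scale φ and the working correlation α from
Pearson residuals at each iteration (Liang–Zeger moment estimators).

Inference uses both the model-based ("naive") covariance B⁻¹ and the robust
sandwich B⁻¹ M B⁻¹, which remains valid if the working correlation is
misspecified.  Model comparison uses QICu = −2·QL + 2p, the quasi-likelihood
criterion for GEEs with a fixed working-correlation structure.

Exchangeable working-covariance inverses use the closed-form rank-1
expression R⁻¹ = 1/(1−α) [I − α/(1+(n_i−1)α) J], so the whole fit reduces to
per-cluster sums and never forms a dense n_i × n_i matrix.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DesignMatrix, ModelSpec, SpecificationError

_PIN_EPS = 1e-10  # fitted risks this close to 0/1 flag possible separation
_MU_CLAMP = 1e-12


class NonConvergenceWarning(UserWarning):
    pass


class SeparationWarning(UserWarning):
    pass


def cloglog(eta):
    """Risk from the linear predictor: p = 1 − exp(−exp(η)), overflow-safe."""
    eta = np.clip(np.asarray(eta, float), -700.0, 30.0)
    return -np.expm1(-np.exp(eta))


def cloglog_inverse(p):
    """Linear predictor from risk: η = ln(−ln(1−p)); domain (0, 1)."""
    p = np.asarray(p, float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("cloglog_inverse requires risks strictly inside (0, 1)")
    return np.log(-np.log1p(-p))


def _dmu_deta(eta):
    """d p / d η = exp(η − exp(η))."""
    eta = np.clip(np.asarray(eta, float), -700.0, 30.0)
    return np.exp(eta - np.exp(eta))


@dataclasses.dataclass
class GEEFit:
    """A fitted GEE: coefficients, dispersion, covariances and diagnostics."""

    params: pd.Series  # β on the cloglog scale, indexed by design column
    alpha: float  # exchangeable working correlation
    phi: float  # scale (Pearson dispersion)
    naive_cov: pd.DataFrame
    robust_cov: pd.DataFrame
    fitted: np.ndarray  # in-sample risks, clamped inside (0, 1)
    qicu: float
    mse: float
    n_iter: int
    converged: bool
    spec: ModelSpec
    n_obs: int
    n_clusters: int
    score_norm: float  # ‖U(β̂)‖ at the reported solution

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov)), index=self.params.index)

    def naive_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.naive_cov)), index=self.params.index)

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "columns": self.columns,
                "alpha": self.alpha,
                "phi": self.phi,
                "naive_cov": self.naive_cov.to_numpy().tolist(),
                "robust_cov": self.robust_cov.to_numpy().tolist(),
                "qicu": self.qicu,
                "mse": self.mse,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "spec": self.spec.to_dict(),
                "n_obs": self.n_obs,
                "n_clusters": self.n_clusters,
                "score_norm": self.score_norm,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GEEFit":
        d = json.loads(text)
        cols = d["columns"]
        params = pd.Series({c: d["params"][c] for c in cols}, index=cols)
        return cls(
            params=params,
            alpha=d["alpha"],
            phi=d["phi"],
            naive_cov=pd.DataFrame(d["naive_cov"], index=cols, columns=cols),
            robust_cov=pd.DataFrame(d["robust_cov"], index=cols, columns=cols),
            fitted=np.array([]),
            qicu=d["qicu"],
            mse=d["mse"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            spec=ModelSpec.from_dict(d["spec"]),
            n_obs=d["n_obs"],
            n_clusters=d["n_clusters"],
            score_norm=d["score_norm"],
        )


def _cluster_layout(cluster_index: np.ndarray):
    change = np.r_[True, cluster_index[1:] != cluster_index[:-1]]
    starts = np.flatnonzero(change)
    sizes = np.diff(np.r_[starts, len(cluster_index)])
    row_cluster = np.repeat(np.arange(len(starts)), sizes)
    return starts, sizes, row_cluster


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    # pivoted QR exposes which columns are (nearly) collinear
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    deficient = np.flatnonzero(diag <= tol)
    if deficient.size:
        bad = [columns[piv[j]] for j in deficient]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def fit_gee(
    dm: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 200,
    fix_alpha: float | None = None,
    fix_phi: float | None = None,
    start_params: np.ndarray | None = None,
    warn: bool = True,
    polish: bool = True,
) -> GEEFit:
    """Fit the clustered cloglog-binomial GEE with exchangeable correlation.

    φ and α default to moment estimates recomputed every iteration:
    φ = Σe²/(n−p) and α = Σ_i Σ_{j<k} e_ij e_ik / (φ·[Σ_i n_i(n_i−1)/2 − p])
    with Pearson residuals e; either can be fixed (``fix_alpha=0, fix_phi=1``
    reproduces an independence GLM).  Convergence: max|Δβ| < ``tol``.
    Non-convergence is flagged on the result, not raised; fitted risks pinned
    at the boundary trigger a separation warning.
    """
    X = np.ascontiguousarray(dm.X.to_numpy(float))
    y = np.asarray(dm.y, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, dm.columns)
    starts, sizes, row_cluster = _cluster_layout(dm.cluster_index)
    k = len(starts)
    max_size = int(sizes.max())
    pair_count = float(np.sum(sizes * (sizes - 1) / 2))

    if start_params is not None:
        beta = np.asarray(start_params, float).copy()
    else:
        beta = np.zeros(p)
        ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        beta[0] = float(cloglog_inverse(ybar)) if dm.columns[0] == "intercept" else 0.0

    def _moments(e):
        phi = fix_phi if fix_phi is not None else float(e @ e) / (n - p)
        if fix_alpha is not None:
            alpha = fix_alpha
        elif pair_count <= p or max_size == 1:
            alpha = 0.0
        else:
            S = np.add.reduceat(e, starts)
            cross = 0.5 * float(np.sum(S**2) - e @ e)
            alpha = cross / (phi * (pair_count - p))
        lo = -1.0 / (max_size - 1) + 1e-6 if max_size > 1 else -0.999999
        alpha = float(np.clip(alpha, lo, 0.999999))
        return float(phi), alpha

    def _assemble(beta):
        eta = X @ beta
        mu = cloglog(eta)
        mu = np.clip(mu, _MU_CLAMP, 1 - _MU_CLAMP)
        g = _dmu_deta(eta)
        v = mu * (1 - mu)
        sv = np.sqrt(v)
        e = (y - mu) / sv
        return mu, g, sv, e

    alpha = 0.0 if fix_alpha is None else fix_alpha
    phi = 1.0 if fix_phi is None else fix_phi
    converged = False
    it = 0
    delta = np.full(p, np.inf)
    # Phase 1: independence iterations to get a stable start; phase 2: full GEE.
    for phase_alpha_free in (False, True):
        prev_alpha = np.inf
        for _ in range(max_iter):
            it += 1
            mu, g, sv, e = _assemble(beta)
            if phase_alpha_free:
                phi, alpha = _moments(e)
            else:
                phi, alpha = (fix_phi if fix_phi is not None else 1.0), (
                    fix_alpha if fix_alpha is not None else 0.0
                )
            c1 = 1.0 / (1.0 - alpha)
            c2 = -alpha / ((1.0 - alpha) * (1.0 + (sizes - 1) * alpha))  # per cluster
            Xt = X * (g / sv)[:, None]
            Ge = np.add.reduceat(np.column_stack([Xt, e]), starts, axis=0)
            G, Se = Ge[:, :-1], Ge[:, -1]  # cluster column-sums, k x p / k
            B = c1 * (Xt.T @ Xt) + (G * c2[:, None]).T @ G
            score = c1 * (Xt.T @ e) + G.T @ (c2 * Se)
            try:
                delta = np.linalg.solve(B, score)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(delta)):  # divergent fit: flag, stop
                break
            # dampen wild steps (rare; near-separation)
            step = float(np.max(np.abs(delta)))
            if step > 5.0:
                delta *= 5.0 / step
            beta = beta + delta
            alpha_stable = abs(alpha - prev_alpha) < 1e-8
            prev_alpha = alpha
            if float(np.max(np.abs(delta))) < tol and (
                not phase_alpha_free or alpha_stable or fix_alpha is not None
            ):
                if phase_alpha_free or fix_alpha is not None:
                    converged = True
                break
        if fix_alpha is not None and fix_phi is not None and not phase_alpha_free:
            # independence phase *is* the requested model
            converged = converged or float(np.max(np.abs(delta))) < tol
            break

    mu, g, sv, e = _assemble(beta)
    if fix_alpha is None or fix_phi is None:
        phi2, alpha2 = _moments(e)
        phi = fix_phi if fix_phi is not None else phi2
        alpha = fix_alpha if fix_alpha is not None else alpha2
    c1 = 1.0 / (1.0 - alpha)
    c2 = -alpha / ((1.0 - alpha) * (1.0 + (sizes - 1) * alpha))

    # polish: Newton steps at frozen (alpha, phi) drive the estimating-equation
    # residual essentially to zero (quadratic convergence)
    if converged and polish:
        for _ in range(10):
            Xt = X * (g / sv)[:, None]
            G = np.add.reduceat(Xt, starts, axis=0)
            Se = np.add.reduceat(e, starts)
            B = c1 * (Xt.T @ Xt) + (G * c2[:, None]).T @ G
            score = c1 * (Xt.T @ e) + G.T @ (c2 * Se)
            try:
                delta = np.linalg.solve(B, score)
            except np.linalg.LinAlgError:
                break
            beta = beta + delta
            mu, g, sv, e = _assemble(beta)
            if float(np.max(np.abs(delta))) < 1e-13:
                break

    Xt = X * (g / sv)[:, None]
    G = np.add.reduceat(Xt, starts, axis=0)
    Se = np.add.reduceat(e, starts)
    B = (c1 * (Xt.T @ Xt) + (G * c2[:, None]).T @ G) / phi
    score = (c1 * (Xt.T @ e) + G.T @ (c2 * Se)) / phi
    score_norm = float(np.linalg.norm(score))

    # robust sandwich: per-cluster score contributions u_i = D_i' V_i^-1 r_i
    z = c1 * e + c2[row_cluster] * Se[row_cluster]
    U = np.add.reduceat(Xt * z[:, None], starts, axis=0) / phi  # k x p
    M = U.T @ U
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        Binv = np.linalg.pinv(B)
    robust = Binv @ M @ Binv
    robust = (robust + robust.T) / 2
    naive = (Binv + Binv.T) / 2

    pinned = (mu <= _PIN_EPS) | (mu >= 1 - _PIN_EPS)
    if warn and pinned.any():
        warnings.warn(
            f"{int(pinned.sum())} fitted risks pinned at the boundary; "
            "possible quasi-separation",
            SeparationWarning,
            stacklevel=2,
        )
    if warn and not converged:
        warnings.warn(
            f"GEE did not converge in {it} iterations (‖U‖={score_norm:.3g})",
            NonConvergenceWarning,
            stacklevel=2,
        )

    cols = dm.columns
    return GEEFit(
        params=pd.Series(beta, index=cols),
        alpha=float(alpha),
        phi=float(phi),
        naive_cov=pd.DataFrame(naive, index=cols, columns=cols),
        robust_cov=pd.DataFrame(robust, index=cols, columns=cols),
        fitted=mu,
        qicu=qicu(y, mu, p),
        mse=fit_mse(y, mu),
        n_iter=it,
        converged=converged,
        spec=dm.spec,
        n_obs=n,
        n_clusters=k,
        score_norm=score_norm,
    )


def robust_covariance(fit: GEEFit) -> pd.DataFrame:
    """The cluster-robust sandwich covariance B⁻¹ M B⁻¹ of a fit."""
    return fit.robust_cov


def qicu(y: np.ndarray, mu: np.ndarray, p: int) -> float:
    """QICu = −2·QL + 2p with the independence binomial quasi-likelihood QL.

    Fitted values at exactly 0/1 are clamped to 1e-12 from the boundary (with
    a warning) so the criterion stays finite.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        warnings.warn("fitted values clamped away from 0/1 for QICu", stacklevel=2)
    mu = np.clip(mu, _MU_CLAMP, 1 - _MU_CLAMP)
    ql = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return -2.0 * ql + 2.0 * p


def fit_mse(y: np.ndarray, mu: np.ndarray) -> float:
    """Mean squared prediction error (Brier score) of fitted risks."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return float(np.mean((y - mu) ** 2))


def predict_probability(
    fit: GEEFit,
    newdata: DesignMatrix | pd.DataFrame,
    params: Mapping[str, float] | pd.Series | None = None,
) -> np.ndarray:
    """Population-averaged risk cloglog(Xβ) for new design rows.

    ``params`` overrides the fit's coefficients (used for model-averaged
    coefficient vectors); columns must match the fitted design exactly.
    """
    X = newdata.X if isinstance(newdata, DesignMatrix) else newdata
    beta = fit.params if params is None else pd.Series(params)
    if list(X.columns) != list(beta.index):
        missing = set(beta.index) - set(X.columns)
        extra = set(X.columns) - set(beta.index)
        raise SpecificationError(
            f"design columns do not match fit: missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    return cloglog(X.to_numpy(float) @ beta.to_numpy(float))
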