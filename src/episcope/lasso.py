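"""L1-penalized feature selection over the stable probes.

Fits the squared-error LASSO

    J(b0, b) = (2n)^-1 * sum_i (y_i - b0 - x_i'b)^2 + alpha * ||b||_1

on the t0 beta matrix with the 0/1 in-hospital outcome as response
(non_survivor = 1), by cyclic coordinate descent with soft-thresholding and
an active-set strategy (coordinates enter the working set when their
gradient violates the KKT bound, are swept to convergence, and a full
KKT pass certifies the solution). The intercept is unpenalized.

Predictors are z-scored by default; with beta values in [0, 1] and a 0/1
response the null-solution KKT bound caps the unstandardized penalty at
max_j |cov(x_j, y)| <= 0.25 * range(x), so the upper end of the
conventional alpha grid (0.2, 0.25) can only ever select features on the
standardized scale. Reported coefficients are on the scale the model was
fit on. ``standardize=False`` restores raw-scale fitting.

``alpha = 0`` is treated as "no selection": all input features are marked
retained rather than attempting an unpenalized fit of an n << p system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

__all__ = [
    "PAPER_ALPHA_GRID",
    "LassoFit",
    "LassoPath",
    "fit_lasso",
    "fit_lasso_path",
    "build_feature_table",
    "kkt_violation",
]

#: the conventional alpha grid for this analysis
PAPER_ALPHA_GRID = (0.0, 0.00001, 0.05, 0.1, 0.2, 0.25)

COEF_EPS = 1e-10  # |coef| above this counts as selected


def _cd_kernel(X, y, beta, alpha, col_norms, max_sweeps, tol):
    """Cyclic coordinate descent on centered data; returns sweeps used.

    Operates in place on ``beta``. ``col_norms[j]`` is (1/n) * sum_i X_ij^2.
    """
    n, p = X.shape
    r = y - X @ beta
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if col_norms[j] == 0.0:
                continue
            bj = beta[j]
            rho = (X[:, j] @ r) / n + col_norms[j] * bj
            if rho > alpha:
                bnew = (rho - alpha) / col_norms[j]
            elif rho < -alpha:
                bnew = (rho + alpha) / col_norms[j]
            else:
                bnew = 0.0
            if bnew != bj:
                r += X[:, j] * (bj - bnew)
                beta[j] = bnew
                d = abs(bnew - bj)
                if d > max_delta:
                    max_delta = d
        if max_delta < tol:
            return sweep + 1
    return max_sweeps


try:  # optional JIT; the pure-numpy kernel is the reference implementation
    from numba import njit as _njit

    _cd_kernel_jit = _njit(cache=False)(_cd_kernel)
except Exception:  # pragma: no cover - numba simply absent
    _cd_kernel_jit = None


@dataclass
class LassoFit:
    """One converged coordinate-descent fit at a single alpha."""

    alpha: float
    coef: np.ndarray  # on the fitting scale (standardized if standardize=True)
    intercept: float
    standardize: bool
    x_mean: np.ndarray
    x_scale: np.ndarray  # ones when standardize=False
    n_sweeps: int
    converged: bool

    @property
    def n_features(self) -> int:
        return int(np.sum(np.abs(self.coef) > COEF_EPS))

    def predict(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.intercept + Xs @ self.coef


def fit_lasso(
    X,
    y,
    alpha: float,
    *,
    standardize: bool = True,
    tol: float = 1e-7,
    max_sweeps: int = 20_000,
    warm_start: np.ndarray | None = None,
) -> LassoFit:
    """Fit the (2n)^-1 squared-error LASSO at one alpha."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")

    x_mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof 0
    x_scale = np.where(sd > 0, sd, 1.0) if standardize else np.ones(p)
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean
    col_norms = (Xc * Xc).sum(axis=0) / n

    beta = np.zeros(p) if warm_start is None else warm_start.astype(float).copy()
    kernel = _cd_kernel_jit if _cd_kernel_jit is not None else _cd_kernel

    # active-set outer loop: sweep the working set to convergence, then do a
    # vectorized KKT pass over all coordinates to admit violators
    active = np.abs(beta) > 0
    total_sweeps = 0
    converged = False
    for _outer in range(100):
        grad = Xc.T @ (yc - Xc @ beta) / n
        violating = (~active) & (np.abs(grad) > alpha * (1 + 1e-12) + tol)
        if _outer > 0 and not violating.any():
            converged = True
            break
        active |= violating
        idx = np.where(active)[0]
        if idx.size == 0:
            converged = True
            break
        sub_beta = beta[idx]
        sweeps = kernel(
            np.asfortranarray(Xc[:, idx]), yc, sub_beta, alpha, col_norms[idx], max_sweeps, tol
        )
        beta[idx] = sub_beta
        total_sweeps += int(sweeps)
        if sweeps >= max_sweeps:
            break
    # predictions are intercept + ((X - x_mean)/x_scale) @ beta, so with the
    # unpenalized intercept the optimum is simply mean(y)
    intercept = y_mean
    return LassoFit(
        alpha=float(alpha),
        coef=beta,
        intercept=intercept,
        standardize=standardize,
        x_mean=x_mean,
        x_scale=x_scale,
        n_sweeps=total_sweeps,
        converged=converged,
    )


def objective(fit: LassoFit, X, y) -> float:
    """J(b0, b) on the fitting scale — exposed for monotonicity checks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - fit.predict(X)
    n = X.shape[0]
    return float((resid @ resid) / (2 * n) + fit.alpha * np.sum(np.abs(fit.coef)))


def kkt_violation(fit: LassoFit, X, y) -> float:
    """Worst-case KKT residual of a fit (0 at the exact solution).

    For zero coefficients the smooth-part gradient must satisfy
    |g_j| <= alpha; for nonzero ones g_j = alpha * sign(b_j).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Xc = (X - fit.x_mean) / fit.x_scale
    yc = y - y.mean()
    grad = Xc.T @ (yc - Xc @ fit.coef) / n
    nz = np.abs(fit.coef) > COEF_EPS
    v_zero = np.max(np.abs(grad[~nz]) - fit.alpha, initial=0.0)
    v_nz = np.max(np.abs(grad[nz] - fit.alpha * np.sign(fit.coef[nz])), initial=0.0)
    return float(max(v_zero, v_nz))


@dataclass
class LassoPath:
    """Per-alpha fits, selected features and tuning diagnostics."""

    alphas: list[float]
    probe_ids: list[str]
    fits: dict[float, LassoFit | None]  # None for the alpha = 0 convention
    cv_mse: dict[float, float]
    standardize: bool
    outcome_coding: dict[str, int] = field(
        default_factory=lambda: {"survivor": 0, "non_survivor": 1}
    )

    def selected(self, alpha: float) -> dict[str, float]:
        """probe_id -> coefficient for features selected at ``alpha``.

        At alpha = 0 every input feature is retained by convention
        (coefficient reported as NaN: no penalized fit is performed).
        """
        if alpha == 0.0:
            return {p: float("nan") for p in self.probe_ids}
        fit = self.fits[alpha]
        nz = np.abs(fit.coef) > COEF_EPS
        return {self.probe_ids[j]: float(fit.coef[j]) for j in np.where(nz)[0]}

    def n_features(self, alpha: float) -> int:
        return len(self.probe_ids) if alpha == 0.0 else self.fits[alpha].n_features

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "n_features": [self.n_features(a) for a in self.alphas],
                "cv_mse": [self.cv_mse.get(a, float("nan")) for a in self.alphas],
            }
        )


def fit_lasso_path(
    X,
    y,
    probe_ids,
    alphas=PAPER_ALPHA_GRID,
    *,
    standardize: bool = True,
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-7,
) -> LassoPath:
    """Fit the LASSO across an alpha grid (warm-started, descending alpha).

    ``cv_folds > 1`` adds a cross-validated prediction-MSE per alpha (the
    alpha-tuning diagnostic); ``cv_folds = 0`` skips it. Requires both
    outcome classes present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    probe_ids = list(probe_ids)
    if X.shape[1] != len(probe_ids):
        raise ValueError("probe_ids length does not match X columns")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome vector is single-class")
    if np.min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need >= 2 samples per outcome class")

    alphas = [float(a) for a in alphas]
    fits: dict[float, LassoFit | None] = {}
    warm = None
    for a in sorted([a for a in alphas if a > 0.0], reverse=True):
        fit = fit_lasso(X, y, a, standardize=standardize, tol=tol, warm_start=warm)
        warm = fit.coef
        fits[a] = fit
    if 0.0 in alphas:
        fits[0.0] = None

    cv_mse: dict[float, float] = {}
    if cv_folds and cv_folds > 1:
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for a in alphas:
            if a == 0.0:
                cv_mse[a] = float("nan")  # no model is fit at alpha = 0
                continue
            errs = []
            for tr_idx, te_idx in kf.split(X):
                f = fit_lasso(X[tr_idx], y[tr_idx], a, standardize=standardize, tol=tol)
                resid = y[te_idx] - f.predict(X[te_idx])
                errs.append(resid @ resid / len(te_idx))
            cv_mse[a] = float(np.mean(errs))

    return LassoPath(
        alphas=alphas, probe_ids=probe_ids, fits=fits, cv_mse=cv_mse, standardize=standardize
    )


def build_feature_table(
    path: LassoPath,
    X,
    y,
    manifest: pd.Series,
    *,
    alphas=None,
) -> pd.DataFrame:
    """Selected-feature table: coefficients per alpha plus Mann–Whitney p.

    Rows are the union of features selected at any of the listed ``alphas``
    (default: the path's selective alphas, i.e. those > 0.01 — the
    no-selection alpha 0 and the near-zero alpha would list everything).
    ``mwu_p`` compares each probe's t0 beta values between outcome groups;
    ``in_list_count`` counts the alphas selecting the probe. Sorted by
    in_list_count descending, then probe_id.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if alphas is None:
        alphas = [a for a in path.alphas if a > 0.01]
    sel = {a: path.selected(a) for a in alphas}
    union = sorted(set().union(*[s.keys() for s in sel.values()]) if sel else set())
    col_of = {p: j for j, p in enumerate(path.probe_ids)}

    rows = []
    for probe in union:
        xj = X[:, col_of[probe]]
        mwu = mann_whitney_u(xj[y == 1], xj[y == 0])
        row = {
            "probe_id": probe,
            "gene_annotation": manifest.get(probe, ""),
            "mwu_p": mwu.p_two_sided,
        }
        count = 0
        for a in alphas:
            coef = sel[a].get(probe)
            row[f"coef_alpha_{a:g}"] = coef if coef is not None else float("nan")
            count += coef is not None
        row["in_list_count"] = count
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["in_list_count", "probe_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return table
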