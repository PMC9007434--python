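"""Partially penalized estimation of the causal effect.

The estimator minimizes, over (theta, delta),

    (1/2) (beta_y - theta*beta_x - beta_w delta)' S (beta_y - theta*beta_x - beta_w delta)
        + lambda * ||delta||_1,

penalizing the covariate pleiotropy coefficients delta while leaving the
causal effect theta unpenalized.  This is solved exactly by a two-step
procedure:

1. project the weighted outcome associations onto the orthocomplement of
   the weighted risk-factor association vector b = S^{1/2} beta_x using the
   annihilator P = I - b b' / (b'b), and solve a *standard* Lasso for delta
   on the projected working data;
2. recover theta in closed form as the IVW estimate applied to the
   pleiotropy-corrected outcome associations beta_y - beta_w delta_hat.

Penalty convention
------------------
The Lasso step minimizes (1/(2m)) * RSS + lambda * ||delta_std||_1 with
m = p working observations and columns of the working design standardized
to unit standard deviation before fitting (coefficients are transformed
back afterwards).  This is the glmnet convention; lambda values reported by
this package are on that scale and are not transferable to solvers with a
different scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .estimators import DegenerateInstrumentError, ivw, mv_ivw
from .summary import FitResult, SummaryData

__all__ = [
    "Projection",
    "RegPath",
    "projection",
    "lasso_delta",
    "lasso_path_delta",
    "theta_from_delta",
    "fit_reg",
    "reg_path",
    "post_reg",
    "joint_objective",
]

# Coordinate-descent controls.  Single-lambda fits target a duality gap of
# 1e-9 relative to ||y||^2 and, if coordinate descent stalls (it can on
# ill-conditioned, nearly unpenalized problems at the dense tail of the
# grid), are polished by a quasi-Newton solve of the equivalent
# positive-part-split quadratic program.  Full paths (the cross-validation
# workhorse) use a looser 1e-7 target and a capped sweep budget: CV only
# needs the error curve, not last-digit coefficients.
LASSO_TOL = 1e-9
PATH_TOL = 1e-5
LASSO_MAX_ITER = 50_000
PATH_MAX_ITER = 1_000
_ZERO_VAR = 1e-12


@dataclass
class Projection:
    """The p x p annihilator of the weighted risk-factor direction."""

    matrix: np.ndarray


@dataclass
class RegPath:
    """delta and theta estimates along a decreasing lambda grid."""

    lambdas: np.ndarray
    delta_path: np.ndarray  # k x L
    theta_path: np.ndarray  # L
    active_sets: list  # per-lambda tuple of covariate indices


def _weighted_direction(data: SummaryData) -> tuple[np.ndarray, float]:
    b = data.beta_x / data.se_y  # S^{1/2} beta_x
    btb = float(b @ b)
    if btb <= 0.0 or not np.any(data.beta_x):
        raise DegenerateInstrumentError("beta_x' S beta_x is zero")
    return b, btb


def projection(data: SummaryData) -> Projection:
    """Explicit matrix P = I_p - S^{1/2} beta_x (beta_x' S beta_x)^{-1} beta_x' S^{1/2}.

    P is symmetric, idempotent, of rank p - 1, and annihilates S^{1/2} beta_x.
    The solvers below apply P implicitly; the explicit form is exposed for
    inspection and testing.
    """
    b, btb = _weighted_direction(data)
    return Projection(np.eye(data.p) - np.outer(b, b) / btb)


def _working(data: SummaryData) -> tuple[np.ndarray, np.ndarray]:
    """Working response P S^{1/2} beta_y and design P S^{1/2} beta_w."""
    b, btb = _weighted_direction(data)
    sy = data.beta_y / data.se_y
    sw = data.beta_w / data.se_y[:, None]
    ytil = sy - b * (b @ sy) / btb
    xtil = sw - np.outer(b, b @ sw) / btb
    return ytil, xtil


def _scales(xtil: np.ndarray, standardize: bool) -> np.ndarray:
    """Per-column standardization factors; zero-variance columns get scale 0
    (their coefficients are pinned at zero)."""
    if not standardize:
        s = np.ones(xtil.shape[1])
        s[np.linalg.norm(xtil, axis=0) < _ZERO_VAR] = 0.0
        return s
    s = xtil.std(axis=0, ddof=0)
    s[s < _ZERO_VAR * max(1.0, float(np.abs(xtil).max(initial=0.0)))] = 0.0
    return s


def _split_qp_polish(
    X: np.ndarray, y: np.ndarray, lam: float, start: np.ndarray
) -> np.ndarray:
    """Polish a Lasso solution by L-BFGS-B on the positive-part split
    d = a - b, a, b >= 0, which makes (1/(2m))||y - Xd||^2 + lam*||d||_1 a
    smooth bound-constrained quadratic program."""
    from scipy.optimize import minimize

    m, k = X.shape
    z0 = np.concatenate([np.clip(start, 0, None), np.clip(-start, 0, None)])

    def fun(z):
        d = z[:k] - z[k:]
        r = y - X @ d
        g_d = -(X.T @ r) / m
        grad = np.concatenate([g_d + lam, -g_d + lam])
        return 0.5 * (r @ r) / m + lam * z.sum(), grad

    res = minimize(
        fun, z0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
    )
    d = res.x[:k] - res.x[k:]
    # compare on the common objective; keep whichever is better
    def obj(dd):
        r = y - X @ dd
        return 0.5 * (r @ r) / m + lam * np.abs(dd).sum()

    return d if obj(d) < obj(start) else start


def lasso_path_delta(
    data: SummaryData,
    lambdas: np.ndarray,
    standardize: bool = True,
    tol: float = PATH_TOL,
    max_iter: int = PATH_MAX_ITER,
    polish: bool = False,
) -> np.ndarray:
    """delta estimates (k x L) along a decreasing lambda grid.

    Solves the Step-1 Lasso at every grid value with warm starts from large
    to small lambda.  ``lambdas == 0`` entries are solved as unpenalized
    (minimum-norm) least squares on the working data.  With ``polish``,
    any grid value where coordinate descent leaves a non-negligible duality
    gap is refined by a bound-constrained quasi-Newton solve.
    """
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any(lambdas < 0):
        raise ValueError("lambda must be nonnegative")
    ytil, xtil = _working(data)
    scales = _scales(xtil, standardize)
    live = scales > 0.0
    out = np.zeros((data.k, lambdas.size))
    if not live.any():
        return out

    # Fortran order + explicit float64 lets the solver skip per-alpha
    # input validation, which otherwise dominates CV runtime
    xstd = np.asfortranarray(xtil[:, live] / scales[live], dtype=np.float64)
    ycd = np.ascontiguousarray(ytil, dtype=np.float64)
    pos = lambdas > 0.0
    if pos.any():
        order = np.argsort(lambdas[pos])[::-1]
        alphas = lambdas[pos][order]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, gaps = _sk_lasso_path(
                xstd, ycd, alphas=alphas, tol=tol, max_iter=max_iter,
                check_input=False,
            )
        if polish:
            gaps = np.asarray(gaps)
            for j in np.flatnonzero(gaps > tol * max(1.0, float(ycd @ ycd))):
                coefs[:, j] = _split_qp_polish(xstd, ycd, alphas[j], coefs[:, j])
        dest = np.flatnonzero(pos)[order]
        out[np.ix_(live, dest)] = coefs / scales[live, None]
    if (~pos).any():
        delta0, *_ = np.linalg.lstsq(xtil[:, live], ytil, rcond=None)
        out[np.ix_(live, np.flatnonzero(~pos))] = delta0[:, None]
    return out


def lasso_delta(data: SummaryData, lam: float, standardize: bool = True) -> np.ndarray:
    """Exact minimizer of the Step-1 Lasso objective at a single lambda."""
    return lasso_path_delta(
        data, np.array([lam]), standardize=standardize,
        tol=LASSO_TOL, max_iter=LASSO_MAX_ITER, polish=True,
    )[:, 0]


def theta_from_delta(data: SummaryData, delta: np.ndarray) -> float:
    """Step 2: theta = ((beta_y - beta_w delta)' S beta_x) / (beta_x' S beta_x)."""
    return float(_theta_from_deltas(data, np.asarray(delta, dtype=float).reshape(-1, 1))[0])


def _theta_from_deltas(data: SummaryData, deltas: np.ndarray) -> np.ndarray:
    """Vectorized Step 2 over the columns of a k x L delta matrix."""
    w = data.weights
    den = float(w @ data.beta_x**2)
    if den <= 0.0:
        raise DegenerateInstrumentError("beta_x' S beta_x is zero")
    wx = w * data.beta_x
    return (wx @ (data.beta_y[:, None] - data.beta_w @ deltas)) / den


def joint_objective(
    data: SummaryData, theta: float, delta: np.ndarray, lam: float,
    penalty_weights: np.ndarray | None = None,
) -> float:
    """Value of the joint partially penalized objective on the solver's scale:

    (1/(2p)) * r' S r + lam * sum_j w_j |delta_j|,  r = beta_y - theta*beta_x - beta_w delta.

    ``penalty_weights`` defaults to the working-design column standard
    deviations (the standardized-fit penalty); pass ones for the plain,
    unstandardized objective.
    """
    delta = np.asarray(delta, dtype=float).ravel()
    if penalty_weights is None:
        _, xtil = _working(data)
        penalty_weights = _scales(xtil, standardize=True)
    r = data.beta_y - theta * data.beta_x - data.beta_w @ delta
    return float(
        0.5 * (data.weights @ r**2) / data.p
        + lam * np.abs(delta) @ np.asarray(penalty_weights, dtype=float)
    )


def _reg_se(data: SummaryData, delta: np.ndarray) -> tuple[float, float]:
    """Heuristic SE for the regularized estimate: IVW-model SE on the
    pleiotropy-corrected outcome associations (ignores selection and
    shrinkage uncertainty; see the methods note)."""
    w = data.weights
    den = float(w @ data.beta_x**2)
    y_corr = data.beta_y - data.beta_w @ delta
    theta = float((w * data.beta_x) @ y_corr) / den
    resid = y_corr - theta * data.beta_x
    df = data.p - 1 - int(np.count_nonzero(delta))
    phi = max(1.0, float(w @ resid**2) / df) if df > 0 else 1.0
    return float(np.sqrt(phi / den)), float(np.sqrt(phi))


def fit_reg(
    data: SummaryData, lam: float, standardize: bool = True, level: float = 0.95
) -> FitResult:
    """Two-step regularized fit at a fixed lambda (method tag ``Reg``)."""
    delta = lasso_delta(data, lam, standardize=standardize)
    theta = theta_from_delta(data, delta)
    se, disp = _reg_se(data, delta)
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return FitResult(
        theta_hat=theta,
        se_theta=se,
        ci_low=theta - z * se,
        ci_high=theta + z * se,
        method="Reg",
        delta_hat=delta,
        selected=tuple(np.flatnonzero(delta).tolist()),
        lambda_used=float(lam),
        dispersion=disp,
        level=level,
    )


def reg_path(
    data: SummaryData,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    standardize: bool = True,
) -> RegPath:
    """Regularization path along a decreasing lambda grid (default: the
    100-value glmnet-style grid from :func:`mrpleio.tuning.lambda_grid`)."""
    if lambdas is None:
        from .tuning import lambda_grid

        lambdas = lambda_grid(data, n_lambda=n_lambda, standardize=standardize)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    deltas = lasso_path_delta(data, lambdas, standardize=standardize)
    thetas = _theta_from_deltas(data, deltas)
    active = [tuple(np.flatnonzero(deltas[:, l]).tolist()) for l in range(lambdas.size)]
    return RegPath(lambdas=lambdas, delta_path=deltas, theta_path=thetas, active_sets=active)


def post_reg(
    data: SummaryData, lam: float, standardize: bool = True, level: float = 0.95
) -> FitResult:
    """Post-regularization estimator: unpenalized multivariable IVW refit on
    the Lasso-selected covariate support (method tag ``Post-reg``).

    Removes the shrinkage bias of the penalized fit at some cost in
    efficiency.  If the selected support is too large to refit (cannot occur
    for validated inputs, where k <= p - 1), the shrunken estimate is
    returned with a warning.
    """
    delta = lasso_delta(data, lam, standardize=standardize)
    support = tuple(np.flatnonzero(delta).tolist())
    if 1 + len(support) > data.p:
        warnings.warn(
            "selected support too large for an unpenalized refit; "
            "returning the regularized estimate",
            RuntimeWarning,
        )
        fit = fit_reg(data, lam, standardize=standardize, level=level)
        return FitResult(
            **{**fit.__dict__, "method": "Post-reg"}
        )
    fit = mv_ivw(data, support, level=level) if support else ivw(data, level=level)
    return FitResult(
        theta_hat=fit.theta_hat,
        se_theta=fit.se_theta,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        method="Post-reg",
        delta_hat=fit.delta_hat,
        selected=support,
        lambda_used=float(lam),
        dispersion=fit.dispersion,
        level=level,
    )
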