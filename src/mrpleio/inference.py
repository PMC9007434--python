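"""Confidence intervals and selection-aware estimation strategies.

Refitting an unpenalized model on a Lasso-selected covariate set and then
reading off its standard error ignores the selection event, so two-sample
post-regularization intervals tend to undercover.  Two pragmatic remedies
are provided:

* the three-sample design, where an independent set of genetic
  associations is used only to select the covariates and a standard
  two-sample multivariable analysis is run on separate data; and
* double estimation, where two fully penalized Lassos select covariates
  predicting the exposure associations and the outcome associations
  respectively, and the final model uses the union of the two supports.

Intervals are normal-theory throughout, built on the multiplicative
random-effects standard errors of the estimators module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .estimators import ivw, mv_ivw
from .regularize import (
    LASSO_MAX_ITER,
    LASSO_TOL,
    PATH_MAX_ITER,
    PATH_TOL,
    lasso_delta,
)
from .summary import FitResult, SummaryData
from .tuning import GRID_RATIO_LARGE, GRID_RATIO_SMALL, cv_lambda

__all__ = ["ThreeSampleInputs", "ci_normal", "three_sample_fit", "double_selection"]


@dataclass
class ThreeSampleInputs:
    """Independent selection and analysis summary datasets over the same
    variants and covariates, in the same order."""

    selection: SummaryData
    analysis: SummaryData

    def __post_init__(self) -> None:
        if self.selection.variant_ids != self.analysis.variant_ids:
            raise ValueError("selection and analysis data must share variants and order")
        if self.selection.covariate_names != self.analysis.covariate_names:
            raise ValueError("selection and analysis data must share covariates and order")


def ci_normal(fit: FitResult, level: float = 0.95) -> FitResult:
    """Normal-theory interval theta_hat +/- z_{(1+level)/2} * se_theta."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    if fit.se_theta < 0:
        raise ValueError("se_theta must be nonnegative")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return replace(
        fit,
        ci_low=fit.theta_hat - z * fit.se_theta,
        ci_high=fit.theta_hat + z * fit.se_theta,
        level=level,
    )


def three_sample_fit(
    inputs: ThreeSampleInputs,
    K: int = 10,
    repeats: int = 1,
    seed: int | None = None,
    use_mean_min: bool = False,
    level: float = 0.95,
) -> FitResult:
    """Select covariates by the regularized fit with CV lambda on the
    selection data only, then fit multivariable IVW on the analysis data.

    Passing the same object as both selection and analysis data is
    permitted (it collapses to two-sample post-regularization) and flagged
    via the method tag suffix.
    """
    try:
        cv = cv_lambda(inputs.selection, K=K, repeats=repeats, seed=seed)
    except ValueError:
        # degenerate selection data: nothing correlates with the projected
        # outcome associations, so there is no pleiotropy signal to select
        cv = None
    if cv is None:
        lam, support = 0.0, ()
    else:
        lam = cv.lambda_mean_min if use_mean_min else cv.lambda_min
        delta = lasso_delta(inputs.selection, lam)
        support = tuple(np.flatnonzero(delta).tolist())
    fit = mv_ivw(inputs.analysis, support, level=level) if support else ivw(
        inputs.analysis, level=level
    )
    tag = "ThreeSample"
    if inputs.selection is inputs.analysis:
        tag += " (degenerate: selection == analysis)"
    return replace(fit, method=tag, lambda_used=float(lam), selected=support)


def _std_lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    rng: np.random.Generator,
    n_lambda: int = 100,
) -> tuple[np.ndarray, float]:
    """Standard (fully penalized, no-intercept) Lasso with K-fold CV lambda.

    Columns are standardized to unit SD internally; returns the support on
    the original scale and the chosen lambda (glmnet scale).
    """
    m, k = X.shape
    scales = X.std(axis=0, ddof=0)
    live = scales > 1e-12 * max(1.0, float(np.abs(X).max(initial=0.0)))
    if not live.any():
        return np.array([], dtype=int), 0.0
    xs = X[:, live] / scales[live]
    lmax = float(np.max(np.abs(xs.T @ y))) / m
    if lmax <= 0.0:
        return np.array([], dtype=int), 0.0
    ratio = GRID_RATIO_LARGE if m >= k else GRID_RATIO_SMALL
    grid = np.geomspace(lmax, lmax * ratio, n_lambda)

    folds = [np.sort(f) for f in np.array_split(rng.permutation(m), K)]
    curves = np.empty((K, n_lambda))
    for i, heldout in enumerate(folds):
        tr = np.setdiff1d(np.arange(m), heldout)
        _, coefs, _ = _sk_lasso_path(
            np.asfortranarray(xs[tr]), np.ascontiguousarray(y[tr]), alphas=grid,
            tol=PATH_TOL, max_iter=PATH_MAX_ITER, check_input=False,
        )
        resid = y[heldout, None] - xs[heldout] @ coefs
        curves[i] = (resid**2).mean(axis=0)
    lam = float(grid[int(np.argmin(curves.mean(axis=0)))])
    _, coefs, _ = _sk_lasso_path(
        np.asfortranarray(xs), np.ascontiguousarray(y), alphas=np.array([lam]),
        tol=LASSO_TOL, max_iter=LASSO_MAX_ITER, check_input=False,
    )
    support = np.flatnonzero(live)[np.flatnonzero(coefs[:, 0])]
    return support, lam


def double_selection(
    data: SummaryData,
    K: int = 10,
    seed: int | None = None,
    n_lambda: int = 100,
    level: float = 0.95,
) -> FitResult:
    """Double-estimation fit: union of the supports of two standard Lassos.

    The first Lasso regresses beta_x on beta_w (unweighted); the second
    regresses beta_y on beta_w with rows weighted by se_y^{-1} (folding the
    outcome error model into the design).  Each uses its own CV-chosen
    lambda; the final fit is multivariable IVW on the union support.
    """
    rng = np.random.default_rng(seed)
    supp_x, _ = _std_lasso_cv(data.beta_w, data.beta_x, K, rng, n_lambda)
    sw = data.beta_w / data.se_y[:, None]
    sy = data.beta_y / data.se_y
    supp_y, _ = _std_lasso_cv(sw, sy, K, rng, n_lambda)
    union = tuple(sorted(set(supp_x.tolist()) | set(supp_y.tolist())))
    fit = mv_ivw(data, union, level=level) if union else ivw(data, level=level)
    return replace(fit, method="DoubleSel", selected=union)
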