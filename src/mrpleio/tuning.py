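"""Lambda-grid construction and K-fold cross-validation over variants.

The cross-validation unit is the genetic variant — the "observation" of the
weighted regression of the outcome associations on the risk-factor and
covariate associations.  For each fold and each lambda the two-step
regularized fit on the training variants predicts the held-out outcome
associations as theta_hat * beta_x + beta_w @ delta_hat, and the held-out
error is the se_y^{-2}-weighted mean squared prediction error.

Two selection strategies are exposed: ``lambda_min``, the minimizer of the
pooled CV error curve (used once per simulated replicate), and
``lambda_mean_min``, the arithmetic mean over repeated CV partitions of the
per-repeat minimizers (the more stable choice for a single real dataset,
typically with 100 repeats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .regularize import _scales, _theta_from_deltas, _working, lasso_path_delta
from .summary import SummaryData

__all__ = ["CVResult", "lambda_grid", "cv_lambda"]

#: lambda_min / lambda_max for the log-spaced grid, as in glmnet: the small
#: ratio when working observations exceed penalized dimensions.
GRID_RATIO_LARGE = 1e-4
GRID_RATIO_SMALL = 1e-2


@dataclass
class CVResult:
    """Cross-validation error curve and the lambdas it selects."""

    lambdas: np.ndarray
    cv_mse: np.ndarray  # per-lambda mean held-out weighted squared error
    cv_se: np.ndarray  # per-lambda SD of fold errors
    lambda_min: float
    lambda_mean_min: float
    repeats: int
    K: int
    seed: int | None = None
    grid_ratio: float | None = None


def lambda_grid(
    data: SummaryData,
    n_lambda: int = 100,
    ratio: float | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to lambda_max * ratio.

    lambda_max is the smallest penalty with an all-zero delta: the largest
    absolute inner product of the (standardized) working-design columns with
    the working response, divided by the p working observations.
    """
    ytil, xtil = _working(data)
    scales = _scales(xtil, standardize)
    live = scales > 0.0
    if not live.any():
        raise ValueError("all working-design columns are degenerate after projection")
    xstd = xtil[:, live] / scales[live]
    lmax = float(np.max(np.abs(xstd.T @ ytil))) / data.p
    # inner products at float-rounding scale mean the response carries no
    # covariate signal at all
    noise_floor = 1e-12 * np.linalg.norm(ytil) * np.abs(xstd).max(initial=0.0)
    if lmax <= noise_floor:
        raise ValueError("working response is orthogonal to the working design")
    if ratio is None:
        ratio = GRID_RATIO_LARGE if data.p >= data.k else GRID_RATIO_SMALL
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _fold_indices(p: int, K: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(p)
    return [np.sort(f) for f in np.array_split(perm, K)]


def cv_lambda(
    data: SummaryData,
    K: int = 10,
    repeats: int = 1,
    seed: int | None = None,
    n_lambda: int = 100,
    lambdas: np.ndarray | None = None,
    standardize: bool = True,
) -> CVResult:
    """K-fold cross-validation of the two-step regularized fit over variants.

    The grid is computed once from the full data; each training fit is
    evaluated at the same grid so error curves are comparable across folds.
    Ties in the error curve resolve to the largest (most parsimonious)
    lambda.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if data.p < 2 * K:
        warnings.warn(
            f"p={data.p} variants is small for {K}-fold CV; folds hold out "
            "single variants and error curves will be noisy",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    if lambdas is None:
        lambdas = lambda_grid(data, n_lambda=n_lambda, standardize=standardize)
    lambdas = np.asarray(lambdas, dtype=float)
    L = lambdas.size

    fold_errors: list[np.ndarray] = []
    repeat_minima = np.empty(repeats)
    for rep in range(repeats):
        for attempt in range(100):
            folds = _fold_indices(data.p, K, rng)
            if min(f.size for f in folds) >= 1 and all(data.p - f.size >= 2 for f in folds):
                break
        else:  # pragma: no cover - unreachable for K <= p/2
            raise RuntimeError("could not build valid CV folds")
        rep_curves = np.empty((K, L))
        for i, heldout in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(data.p), heldout)
            train = data.subset(train_idx, validate=False)
            deltas = lasso_path_delta(train, lambdas, standardize=standardize)
            thetas = _theta_from_deltas(train, deltas)
            pred = np.outer(data.beta_x[heldout], thetas) + data.beta_w[heldout] @ deltas
            resid = data.beta_y[heldout, None] - pred
            w = data.weights[heldout]
            rep_curves[i] = (w @ resid**2) / w.sum()
        fold_errors.append(rep_curves)
        repeat_minima[rep] = lambdas[int(np.argmin(rep_curves.mean(axis=0)))]

    all_curves = np.vstack(fold_errors)  # (K*repeats, L)
    cv_mse = all_curves.mean(axis=0)
    cv_se = all_curves.std(axis=0, ddof=1) if all_curves.shape[0] > 1 else np.zeros(L)
    # grid is decreasing, so argmin's first hit is the largest tied lambda
    lambda_min = float(lambdas[int(np.argmin(cv_mse))])
    return CVResult(
        lambdas=lambdas,
        cv_mse=cv_mse,
        cv_se=cv_se,
        lambda_min=lambda_min,
        lambda_mean_min=float(repeat_minima.mean()),
        repeats=repeats,
        K=K,
        seed=seed,
        grid_ratio=float(lambdas[-1] / lambdas[0]),
    )
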