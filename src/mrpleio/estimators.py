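"""Closed-form summary-data estimators: IVW and multivariable IVW.

The inverse-variance weighted (IVW) estimator regresses the variant-outcome
associations on the variant-risk-factor associations through the origin,
weighting each variant by se(beta_y)^{-2}:

    theta_IVW = (beta_x' S beta_y) / (beta_x' S beta_x),

with S = diag(se_y^{-2}).  When variants act on the outcome through measured
covariates (pleiotropy), IVW is inconsistent; multivariable IVW additionally
includes the variant-covariate association columns in the weighted
regression, estimating the direct effect theta adjusted for the covariate
pathways delta.

Standard errors follow the multiplicative random-effects convention of
established summary-data MR software: the weighted-least-squares standard
error is inflated by max(1, sqrt(RSS_w / (p - q))) where q is the number of
fitted coefficients, so over-dispersion widens intervals but apparent
under-dispersion never shrinks them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary import DimensionError, FitResult, SummaryData

__all__ = [
    "CovariateSet",
    "DegenerateInstrumentError",
    "CollinearityError",
    "ivw",
    "mv_ivw",
]

RANK_TOL = 1e-10


class DegenerateInstrumentError(ValueError):
    """The weighted risk-factor association vector has zero norm."""


class CollinearityError(ValueError):
    """The weighted design matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class CovariateSet:
    """An ordered subset of covariate indices with a human-readable label."""

    indices: tuple
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("covariate indices must be unique")


def _resolve_covs(data: SummaryData, covs) -> np.ndarray:
    """Accept a CovariateSet, index sequence, name sequence, or None (=all)."""
    if covs is None:
        return np.arange(data.k)
    if isinstance(covs, CovariateSet):
        idx = np.asarray(covs.indices, dtype=int)
    else:
        covs = list(covs)
        if covs and isinstance(covs[0], str):
            lookup = {n: j for j, n in enumerate(data.covariate_names)}
            idx = np.array([lookup[n] for n in covs], dtype=int)
        else:
            idx = np.asarray(covs, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= data.k):
        raise IndexError(f"covariate index out of range 0..{data.k - 1}")
    return idx


def _interval(theta: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return theta - z * se, theta + z * se


def ivw(data: SummaryData, level: float = 0.95) -> FitResult:
    """Inverse-variance weighted estimate of the causal effect, ignoring
    all covariates."""
    w = data.weights
    den = float(w @ (data.beta_x**2))
    if den <= 0.0 or not np.any(data.beta_x):
        raise DegenerateInstrumentError(
            "beta_x' S beta_x is zero: instruments carry no risk-factor signal"
        )
    theta = float((w * data.beta_x) @ data.beta_y) / den
    resid = data.beta_y - theta * data.beta_x
    rss_w = float(w @ resid**2)
    phi = max(1.0, rss_w / (data.p - 1)) if data.p > 1 else 1.0
    se = float(np.sqrt(phi / den))
    lo, hi = _interval(theta, se, level)
    return FitResult(
        theta_hat=theta,
        se_theta=se,
        ci_low=lo,
        ci_high=hi,
        method="IVW",
        delta_hat=np.zeros(data.k),
        selected=(),
        dispersion=float(np.sqrt(phi)),
        level=level,
    )


def mv_ivw(data: SummaryData, covs=None, level: float = 0.95) -> FitResult:
    """Multivariable IVW: weighted regression through the origin of beta_y on
    [beta_x, beta_w[:, covs]] with weights se_y^{-2}.

    ``covs`` may be a :class:`CovariateSet`, a sequence of covariate indices
    or names, or None for all k covariates.  An empty set reproduces
    :func:`ivw` exactly.
    """
    idx = _resolve_covs(data, covs)
    if idx.size == 0:
        return ivw(data, level=level)

    q = 1 + idx.size
    if q > data.p:
        raise DimensionError(
            f"{idx.size} covariates + risk factor exceed p={data.p} variants"
        )
    X = np.column_stack([data.beta_x, data.beta_w[:, idx]])
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0.0):
        dead = np.flatnonzero(norms == 0.0)
        raise CollinearityError(f"all-zero design column(s) at position(s) {dead.tolist()}")
    if np.linalg.matrix_rank(X / norms, tol=RANK_TOL) < q:
        s = np.linalg.svd(X / norms, compute_uv=False)
        raise CollinearityError(
            f"rank-deficient design for covariates {idx.tolist()} "
            f"(smallest scaled singular value {s[-1]:.2e})"
        )

    res = sm.WLS(data.beta_y, X, weights=data.weights, hasconst=False).fit()
    phi = max(1.0, float(res.scale)) if data.p > q else 1.0
    se = float(np.sqrt(res.normalized_cov_params[0, 0] * phi))
    theta = float(res.params[0])
    delta = np.zeros(data.k)
    delta[idx] = res.params[1:]
    lo, hi = _interval(theta, se, level)
    return FitResult(
        theta_hat=theta,
        se_theta=se,
        ci_low=lo,
        ci_high=hi,
        method="MV-IVW",
        delta_hat=delta,
        selected=tuple(int(i) for i in idx),
        dispersion=float(np.sqrt(phi)),
        level=level,
    )
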