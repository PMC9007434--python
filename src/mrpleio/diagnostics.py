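"""Covariate-balancing diagnostic.

For a candidate covariate set, regress the variant-outcome associations on
the included variant-covariate associations (ordinary least squares with an
intercept) and correlate the residuals with the variant-risk-factor vector
and with every covariate column.  If the covariates in the set account for
the pleiotropy, the residual correlations with all covariate columns are
close to zero, while a strong residual correlation with the risk-factor
associations indicates the instruments retain exposure signal after
adjustment.

Under the default unweighted-OLS convention the correlations for covariates
inside the set are exactly zero, which makes the diagnostic easy to read; a
weighted variant (rows scaled by se_y^{-1} in the residualizing regression)
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import CollinearityError, _resolve_covs
from .summary import SummaryData

__all__ = ["BalanceTable", "balance", "balance_frame"]


@dataclass
class BalanceTable:
    """Residual correlations for one candidate covariate set."""

    covariate_set_label: str
    corr_with_x: float
    corr_with_w: np.ndarray  # length k
    covariate_names: list


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    den = np.sqrt((ac @ ac) * (bc @ bc))
    if den == 0.0:
        return np.nan
    return float(np.clip((ac @ bc) / den, -1.0, 1.0))


def balance(
    data: SummaryData,
    covs=(),
    weighted: bool = False,
    label: str | None = None,
) -> BalanceTable:
    """Residual correlations after adjusting the outcome associations for
    the covariate set ``covs`` (empty set: residuals are the centered
    outcome associations)."""
    idx = _resolve_covs(data, covs)
    if idx.size > data.p - 2:
        raise ValueError(
            f"balance requires at most p - 2 = {data.p - 2} covariates in the set"
        )
    design = np.column_stack([np.ones(data.p), data.beta_w[:, idx]])
    if idx.size and np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            f"covariate columns {idx.tolist()} are collinear in the balance regression"
        )
    if weighted:
        root_w = 1.0 / data.se_y
        coef, *_ = np.linalg.lstsq(design * root_w[:, None], data.beta_y * root_w, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(design, data.beta_y, rcond=None)
    resid = data.beta_y - design @ coef
    corr_w = np.array([_corr(resid, data.beta_w[:, j]) for j in range(data.k)])
    if label is None:
        label = "none" if idx.size == 0 else "+".join(data.covariate_names[j] for j in idx)
    return BalanceTable(
        covariate_set_label=label,
        corr_with_x=_corr(resid, data.beta_x),
        corr_with_w=corr_w,
        covariate_names=list(data.covariate_names),
    )


def balance_frame(data: SummaryData, sets: dict, weighted: bool = False) -> pd.DataFrame:
    """Long-format table (set_label, trait, correlation) over several
    candidate sets, suitable for a dot plot."""
    rows = []
    for label, covs in sets.items():
        tab = balance(data, covs, weighted=weighted, label=label)
        rows.append({"set_label": label, "trait": "risk_factor", "correlation": tab.corr_with_x})
        for name, r in zip(tab.covariate_names, tab.corr_with_w):
            rows.append({"set_label": label, "trait": name, "correlation": r})
    return pd.DataFrame(rows)
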