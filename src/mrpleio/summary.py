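"""Summary-statistic containers and delimited-text I/O.

Everything in this package operates on per-variant GWAS summary statistics:
for each of p genetic variants, its estimated association with the risk
factor (``beta_x``), with each of k measured covariates (``beta_w``, one
column per covariate), with the outcome (``beta_y``, a log odds ratio for
binary outcomes), and the standard error of the outcome association
(``se_y``).  The inverse squared outcome standard errors are the weights of
every downstream regression; exposure/covariate standard errors may be
carried along but are never used in weighting.

Inputs are assumed to be pre-harmonized: all associations refer to the same
effect allele in every column.  Missing values are hard errors — summary MR
tables are small enough that silently dropping rows is more dangerous than
failing loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryData",
    "FitResult",
    "SummaryFormatError",
    "SummaryValidationError",
    "DimensionError",
    "load_summary",
    "write_summary",
    "weight_matrix",
]

#: required input columns and their roles
REQUIRED_COLUMNS = ("snp", "beta_x", "beta_y", "se_y")
COVARIATE_PREFIX = "beta_w_"


class SummaryFormatError(ValueError):
    """The input file does not have the expected layout."""


class SummaryValidationError(ValueError):
    """Parsed values violate a summary-data invariant."""


class DimensionError(ValueError):
    """Identification requires more variants than covariates (p >= k + 1)."""


@dataclass
class SummaryData:
    """Per-variant association estimates for one MR analysis.

    Parameters
    ----------
    variant_ids
        Length-p variant identifiers (e.g. rsids); order is meaningful and
        preserved by all operations.
    beta_x
        Length-p per-allele associations with the risk factor.
    beta_w
        p x k per-allele associations with the k covariates.
    beta_y
        Length-p per-allele associations with the outcome.
    se_y
        Length-p strictly positive standard errors of ``beta_y``.
    covariate_names
        Length-k covariate labels, one per column of ``beta_w``.
    se_x, se_w
        Optional standard errors of the exposure/covariate associations.
        Carried for reporting only; never used in weighting.
    """

    variant_ids: list
    beta_x: np.ndarray
    beta_w: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    covariate_names: list
    se_x: np.ndarray | None = None
    se_w: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.beta_x = np.asarray(self.beta_x, dtype=float).ravel()
        self.beta_y = np.asarray(self.beta_y, dtype=float).ravel()
        self.se_y = np.asarray(self.se_y, dtype=float).ravel()
        self.beta_w = np.atleast_2d(np.asarray(self.beta_w, dtype=float))
        if self.beta_w.shape[0] == 1 and len(self.variant_ids) != 1:
            self.beta_w = self.beta_w.T
        self.covariate_names = [str(c) for c in self.covariate_names]
        if self.se_x is not None:
            self.se_x = np.asarray(self.se_x, dtype=float).ravel()
        if self.se_w is not None:
            self.se_w = np.atleast_2d(np.asarray(self.se_w, dtype=float))
        if not self.meta.get("skip_validation", False):
            self.validate()

    # -- shape accessors ---------------------------------------------------
    @property
    def p(self) -> int:
        """Number of genetic variants."""
        return len(self.variant_ids)

    @property
    def k(self) -> int:
        """Number of measured covariates."""
        return self.beta_w.shape[1]

    def validate(self) -> None:
        p = self.p
        if self.beta_x.shape != (p,) or self.beta_y.shape != (p,) or self.se_y.shape != (p,):
            raise SummaryValidationError(
                f"beta_x/beta_y/se_y must all have length p={p}; got "
                f"{self.beta_x.shape}, {self.beta_y.shape}, {self.se_y.shape}"
            )
        if self.beta_w.shape[0] != p:
            raise SummaryValidationError(
                f"beta_w has {self.beta_w.shape[0]} rows, expected p={p}"
            )
        if len(self.covariate_names) != self.k:
            raise SummaryValidationError(
                f"{len(self.covariate_names)} covariate names for k={self.k} columns"
            )
        for name, arr in (
            ("beta_x", self.beta_x),
            ("beta_w", self.beta_w),
            ("beta_y", self.beta_y),
            ("se_y", self.se_y),
        ):
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr)).ravel()
                raise SummaryValidationError(
                    f"non-finite value in {name} (first at flat index {bad[0]})"
                )
        nonpos = np.flatnonzero(self.se_y <= 0)
        if nonpos.size:
            raise SummaryValidationError(
                f"se_y must be strictly positive; variant "
                f"{self.variant_ids[nonpos[0]]!r} has se_y={self.se_y[nonpos[0]]}"
            )
        if self.k > p - 1:
            raise DimensionError(
                f"k={self.k} covariates with only p={p} variants; identification "
                f"of the causal effect requires p >= k + 1"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        """Inverse-variance weights se_y^{-2} (diagonal of the weight matrix S)."""
        return self.se_y**-2.0

    def subset(self, idx: Sequence[int], validate: bool = True) -> "SummaryData":
        """Row-subset (e.g. a cross-validation fold), preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        meta = dict(self.meta)
        if not validate:
            meta["skip_validation"] = True
        out = SummaryData(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_x=self.beta_x[idx],
            beta_w=self.beta_w[idx, :],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            covariate_names=list(self.covariate_names),
            se_x=None if self.se_x is None else self.se_x[idx],
            se_w=None if self.se_w is None else self.se_w[idx, :],
            meta=meta,
        )
        return out


@dataclass
class FitResult:
    """A causal-effect estimate with its uncertainty and provenance.

    ``delta_hat`` always has length k, with zeros for covariates excluded
    from the fit; ``selected`` is the index set of covariates entering the
    final model.  ``dispersion`` is the multiplicative random-effects
    residual scale factor (floored at 1) used when computing ``se_theta``.
    """

    theta_hat: float
    se_theta: float
    ci_low: float
    ci_high: float
    method: str
    delta_hat: np.ndarray
    selected: tuple
    lambda_used: float | None = None
    dispersion: float = 1.0
    level: float = 0.95

    def __post_init__(self) -> None:
        self.delta_hat = np.asarray(self.delta_hat, dtype=float).ravel()
        self.selected = tuple(int(i) for i in self.selected)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        sel = ",".join(str(i) for i in self.selected) or "-"
        lam = f" lambda={self.lambda_used:.4g}" if self.lambda_used is not None else ""
        return (
            f"{self.method}: theta={self.theta_hat:.4f} (SE {self.se_theta:.4f}) "
            f"{100 * self.level:.0f}% CI ({self.ci_low:.4f}, {self.ci_high:.4f}) "
            f"selected=[{sel}]{lam}"
        )


def weight_matrix(data: SummaryData) -> np.ndarray:
    """Diagonal of the weight matrix S: element j equals ``se_y[j]**-2``."""
    return data.weights


def load_summary(
    path,
    column_map: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    sep: str | None = None,
) -> SummaryData:
    """Read a delimited summary-statistics table.

    The file must contain columns ``snp``, ``beta_x``, ``beta_y``, ``se_y``
    (renameable through ``column_map``, mapping canonical name -> file
    column) and covariate association columns named ``beta_w_<name>``.
    Optional ``se_x`` and ``se_w_<name>`` columns are carried as metadata.
    Comma- and tab-delimited files are auto-detected when ``sep`` is None.
    """
    if sep is None:
        # sniff comma vs tab from the header line; keep the C parser so the
        # round_trip float converter is available
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text
        raise SummaryFormatError(f"could not parse {path}: {exc}") from exc

    colmap = {c: c for c in REQUIRED_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canonical, col in colmap.items():
        if canonical in REQUIRED_COLUMNS and col not in df.columns:
            raise SummaryFormatError(f"missing required column {col!r} in {path}")

    if covariates is not None:
        names = list(covariates)
        wcols = []
        for name in names:
            col = name if name in df.columns else COVARIATE_PREFIX + name
            if col not in df.columns:
                raise SummaryFormatError(f"missing covariate column for {name!r}")
            wcols.append(col)
        names = [c[len(COVARIATE_PREFIX):] if c.startswith(COVARIATE_PREFIX) else c for c in wcols]
    else:
        wcols = [c for c in df.columns if c.startswith(COVARIATE_PREFIX)]
        names = [c[len(COVARIATE_PREFIX):] for c in wcols]

    se_w = None
    se_w_cols = ["se_w_" + n for n in names]
    if all(c in df.columns for c in se_w_cols) and names:
        se_w = df[se_w_cols].to_numpy(dtype=float)
    se_x = df["se_x"].to_numpy(dtype=float) if "se_x" in df.columns else None

    return SummaryData(
        variant_ids=df[colmap["snp"]].tolist(),
        beta_x=df[colmap["beta_x"]].to_numpy(dtype=float),
        beta_w=df[wcols].to_numpy(dtype=float).reshape(len(df), len(wcols)),
        beta_y=df[colmap["beta_y"]].to_numpy(dtype=float),
        se_y=df[colmap["se_y"]].to_numpy(dtype=float),
        covariate_names=names,
        se_x=se_x,
        se_w=se_w,
    )


def write_summary(data: SummaryData, path, sep: str = ",") -> None:
    """Write ``data`` in the layout read by :func:`load_summary` (round-trips
    all numeric fields at full precision)."""
    cols = {
        "snp": data.variant_ids,
        "beta_x": data.beta_x,
        "beta_y": data.beta_y,
        "se_y": data.se_y,
    }
    if data.se_x is not None:
        cols["se_x"] = data.se_x
    for j, name in enumerate(data.covariate_names):
        cols[COVARIATE_PREFIX + name] = data.beta_w[:, j]
    if data.se_w is not None:
        for j, name in enumerate(data.covariate_names):
            cols["se_w_" + name] = data.se_w[:, j]
    # %.17g guarantees binary round-trip of every float64
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")
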