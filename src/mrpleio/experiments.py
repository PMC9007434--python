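"""Simulation-study orchestration: estimator comparisons and CI coverage.

``run_study`` repeats the full pipeline — draw structural parameters,
simulate independent individual-level samples, summarize by per-variant
regression, fit each requested estimator — and reports the mean, standard
deviation, and mean squared error of the causal-effect estimates per
method.  The regularized fits use a fresh 10-fold CV-selected lambda in
every replicate.

``run_coverage`` runs the same pipeline but records, per CI strategy, the
share of replicates whose nominal-level interval contains the true effect
(coverage) and the share excluding zero (power; type-I error when the true
effect is zero).

Replicate seeds are derived from the study seed and the replicate index
through a splittable seed sequence, so results are independent of
execution order and reproducible replicate by replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import ivw, mv_ivw
from .inference import ThreeSampleInputs, double_selection, three_sample_fit
from .regularize import fit_reg, post_reg
from .simulate import scenario_preset, simulate_summary
from .summary import SummaryData
from .tuning import cv_lambda

__all__ = ["StudySpec", "StudyResult", "run_study", "run_coverage"]

logger = logging.getLogger(__name__)

METHODS = ("IVW", "Reg", "Post-reg", "MV-All", "Oracle")
STRATEGIES = ("ivw", "mvall", "oracle", "two-sample", "three-sample", "double")

#: replicate failure budget before the whole study errors out
MAX_FAILURE_FRACTION = 0.01


@dataclass
class StudySpec:
    """One cell of the simulation study."""

    scenario: int
    theta: float
    n_pleiotropic: int
    sparsity_mode: str = "delta_sparse"
    replicates: int = 1000
    methods: tuple = METHODS
    seed: int = 0
    cv_folds: int = 10
    cv_repeats: int = 1
    n_lambda: int = 100
    n_samples: int = 2
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")


@dataclass
class StudyResult:
    """Per-method summaries plus the raw estimates for downstream checks."""

    table: pd.DataFrame  # index: method; columns: mean, sd, mse, n_ok
    estimates: dict  # method -> np.ndarray of per-replicate theta_hat
    spec: StudySpec
    n_failed: int = 0

    def mean(self, method: str) -> float:
        return float(self.table.loc[method, "mean"])

    def sd(self, method: str) -> float:
        return float(self.table.loc[method, "sd"])

    def mse(self, method: str) -> float:
        return float(self.table.loc[method, "mse"])


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def _fit_methods(
    spec: StudySpec, data: SummaryData, pleio: np.ndarray, cv_seed: int
) -> dict:
    """Fit every requested method on one replicate's summary data."""
    out = {}
    needs_reg = bool({"Reg", "Post-reg"} & set(spec.methods))
    if "IVW" in spec.methods:
        out["IVW"] = ivw(data).theta_hat
    if needs_reg:
        cv = cv_lambda(
            data, K=spec.cv_folds, repeats=spec.cv_repeats,
            seed=cv_seed, n_lambda=spec.n_lambda,
        )
        if "Reg" in spec.methods:
            out["Reg"] = fit_reg(data, cv.lambda_min).theta_hat
        if "Post-reg" in spec.methods:
            out["Post-reg"] = post_reg(data, cv.lambda_min).theta_hat
    if "MV-All" in spec.methods:
        out["MV-All"] = mv_ivw(data).theta_hat
    if "Oracle" in spec.methods:
        out["Oracle"] = mv_ivw(data, pleio.tolist()).theta_hat
    return out


def run_study(spec: StudySpec) -> StudyResult:
    """Run the study cell described by ``spec`` and tabulate the estimates.

    Replicate-level numerical failures (e.g. a rank-deficient design) are
    logged and excluded; more than 1% of them aborts the study.
    """
    estimates: dict[str, list] = {m: [] for m in spec.methods}
    n_failed = 0
    for rep in range(spec.replicates):
        rng = _replicate_rng(spec.seed, rep)
        config = scenario_preset(
            spec.scenario, spec.theta, spec.n_pleiotropic, spec.sparsity_mode,
            n_samples=spec.n_samples, **spec.config_overrides,
        )
        try:
            data, params, _ = simulate_summary(config, rng)
            fits = _fit_methods(
                spec, data, params.pleiotropic, cv_seed=int(rng.integers(2**31))
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            n_failed += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            if n_failed > MAX_FAILURE_FRACTION * spec.replicates:
                raise RuntimeError(
                    f"{n_failed} replicate failures out of {rep + 1}: "
                    "study aborted (failure budget 1%)"
                ) from exc
            continue
        for m, v in fits.items():
            estimates[m].append(v)
        if (rep + 1) % 200 == 0:
            logger.info("completed %d/%d replicates", rep + 1, spec.replicates)

    arrays = {m: np.asarray(v) for m, v in estimates.items()}
    rows = []
    for m in spec.methods:
        a = arrays[m]
        rows.append(
            {
                "method": m,
                "mean": a.mean(),
                "sd": a.std(ddof=1) if a.size > 1 else 0.0,
                "mse": float(np.mean((a - spec.theta) ** 2)),
                "n_ok": a.size,
            }
        )
    table = pd.DataFrame(rows).set_index("method")
    return StudyResult(table=table, estimates=arrays, spec=spec, n_failed=n_failed)


def _strategy_fit(
    strategy: str,
    data: SummaryData,
    selection: SummaryData | None,
    pleio: np.ndarray,
    spec: StudySpec,
    cv_seed: int,
    level: float,
):
    if strategy == "ivw":
        return ivw(data, level=level)
    if strategy == "mvall":
        return mv_ivw(data, level=level)
    if strategy == "oracle":
        return mv_ivw(data, pleio.tolist(), level=level) if pleio.size else ivw(
            data, level=level
        )
    if strategy == "two-sample":
        cv = cv_lambda(
            data, K=spec.cv_folds, repeats=spec.cv_repeats,
            seed=cv_seed, n_lambda=spec.n_lambda,
        )
        return post_reg(data, cv.lambda_min, level=level)
    if strategy == "three-sample":
        if selection is None:
            raise ValueError("three-sample strategy requires n_samples >= 3")
        return three_sample_fit(
            ThreeSampleInputs(selection=selection, analysis=data),
            K=spec.cv_folds, repeats=spec.cv_repeats, seed=cv_seed, level=level,
        )
    if strategy == "double":
        return double_selection(data, K=spec.cv_folds, seed=cv_seed, level=level)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def run_coverage(
    spec: StudySpec,
    strategies: tuple = ("two-sample", "three-sample", "oracle"),
    level: float = 0.95,
) -> StudyResult:
    """Empirical CI coverage and power per strategy under ``spec``.

    Coverage is the share of replicates whose interval contains the true
    theta; power is the share whose interval excludes zero (the type-I
    error rate when theta = 0).
    """
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}")
    n_samples = 3 if "three-sample" in strategies else spec.n_samples
    covered: dict[str, list] = {s: [] for s in strategies}
    rejected: dict[str, list] = {s: [] for s in strategies}
    thetas: dict[str, list] = {s: [] for s in strategies}
    n_failed = 0
    for rep in range(spec.replicates):
        rng = _replicate_rng(spec.seed, rep)
        config = scenario_preset(
            spec.scenario, spec.theta, spec.n_pleiotropic, spec.sparsity_mode,
            n_samples=n_samples, **spec.config_overrides,
        )
        try:
            data, params, selection = simulate_summary(config, rng)
            cv_seed = int(rng.integers(2**31))
            fits = {
                s: _strategy_fit(s, data, selection, params.pleiotropic, spec, cv_seed, level)
                for s in strategies
            }
        except (np.linalg.LinAlgError, ValueError) as exc:
            n_failed += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            if n_failed > MAX_FAILURE_FRACTION * spec.replicates:
                raise RuntimeError(
                    f"{n_failed} replicate failures out of {rep + 1}: study aborted"
                ) from exc
            continue
        for s, f in fits.items():
            covered[s].append(f.ci_low <= spec.theta <= f.ci_high)
            rejected[s].append(not (f.ci_low <= 0.0 <= f.ci_high))
            thetas[s].append(f.theta_hat)

    rows = []
    estimates = {}
    for s in strategies:
        a = np.asarray(thetas[s])
        estimates[s] = a
        rows.append(
            {
                "method": s,
                "mean": a.mean(),
                "sd": a.std(ddof=1) if a.size > 1 else 0.0,
                "mse": float(np.mean((a - spec.theta) ** 2)),
                "coverage": float(np.mean(covered[s])),
                "power": float(np.mean(rejected[s])),
                "n_ok": a.size,
            }
        )
    table = pd.DataFrame(rows).set_index("method")
    return StudyResult(table=table, estimates=estimates, spec=spec, n_failed=n_failed)
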