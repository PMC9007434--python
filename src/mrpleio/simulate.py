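"""Individual-level data generation and per-variant summarization.

The generative model is the linear structural model underlying the package:
for individual i with genotype vector G_i (independent variants, each
Binomial(2, pi)), shared confounder U_i and independent standard-normal
noise,

    X_i  = G_i' beta_X + gamma_X U_i + eps_Xi
    W_ij = G_i' beta_Wj + gamma_Wj U_i + eps_Wij,   j = 1..k
    Y_i  = theta X_i + W_i' delta + gamma_Y U_i + eps_Yi.

A covariate j opens a pleiotropic path from the variants to the outcome
only when delta_j != 0 and beta_Wj != 0, so sparsity can live either in the
covariate effects on the outcome (``delta_sparse``: most delta_j are zero)
or in the genetic effects on the covariates (``betaW_sparse``: all delta_j
are nonzero but most beta_W columns are zero).

Summary statistics are produced the way GWAS consortia produce them: a
simple linear regression (with intercept) of the trait on each variant in
turn, per sample, with the exposure/covariate associations and the outcome
associations taken from non-overlapping samples (two-sample design; a third
independent sample supports selection-free inference).

The scenario presets encode the study conditions used throughout the test
suite: 20 000 individuals per sample, minor allele frequency 0.3, unit
confounder loadings on exposure and outcome, 1/k on each covariate, and
uniform effect-size ranges giving roughly 10% of exposure variance
explained by the instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .summary import SummaryData

__all__ = [
    "SimulationConfig",
    "TrueParams",
    "IndividualData",
    "draw_true_params",
    "simulate_individual",
    "summarize",
    "scenario_preset",
    "simulate_summary",
    "marginal_associations",
]

DELTA_SPARSE = "delta_sparse"
BETAW_SPARSE = "betaW_sparse"

#: preset effect-size ranges: scenario -> (beta_x_range, beta_w_range)
_SCENARIO_RANGES = {
    1: ((0.15, 0.3), (-0.2, 0.4)),
    2: ((0.05, 0.12), (-0.1, 0.15)),
}
_SCENARIO_DIMS = {1: (10, 8), 2: (80, 70)}
_EXPECTED_PLEIO = {1: (1, 2, 4), 2: (7, 21, 35)}


@dataclass
class SimulationConfig:
    """All generative parameters for one simulated study arm."""

    p: int
    k: int
    theta: float
    n: int = 20_000
    pi: float = 0.3
    gamma_x: float = 1.0
    gamma_y: float = 1.0
    gamma_w: float | None = None  # defaults to 1/k
    beta_x_range: tuple = (0.15, 0.3)
    beta_w_range: tuple = (-0.2, 0.4)
    n_pleiotropic: int = 1
    delta_range: tuple = (-0.2, 0.3)
    sparsity_mode: str = DELTA_SPARSE
    n_samples: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("allele frequency pi must lie in (0, 1)")
        if self.n_pleiotropic > self.k:
            raise ValueError("n_pleiotropic cannot exceed k")
        if self.k > self.p - 1:
            raise ValueError("identification requires k <= p - 1")
        for rng_ in (self.beta_x_range, self.beta_w_range, self.delta_range):
            if not rng_[0] <= rng_[1]:
                raise ValueError(f"invalid interval {rng_}")
        if self.sparsity_mode not in (DELTA_SPARSE, BETAW_SPARSE):
            raise ValueError(f"unknown sparsity_mode {self.sparsity_mode!r}")
        if self.gamma_w is None:
            self.gamma_w = 1.0 / self.k


@dataclass
class TrueParams:
    """One draw of the structural parameters."""

    beta_x: np.ndarray
    beta_w: np.ndarray
    delta: np.ndarray
    theta: float

    @property
    def pleiotropic(self) -> np.ndarray:
        """Indices of covariates that open a pleiotropic path (delta_j != 0
        and beta_Wj != 0)."""
        return np.flatnonzero((self.delta != 0) & np.any(self.beta_w != 0, axis=0))


@dataclass
class IndividualData:
    """One individual-level sample from the structural model."""

    genotypes: np.ndarray  # n x p, in {0,1,2}
    x: np.ndarray
    w: np.ndarray  # n x k
    y: np.ndarray
    confounder: np.ndarray


def draw_true_params(config: SimulationConfig, rng: np.random.Generator) -> TrueParams:
    """Draw structural parameters: beta_X and beta_W elementwise uniform on
    their ranges, nonzero delta uniform on ``delta_range``, with the
    pleiotropic covariate indices chosen uniformly without replacement."""
    beta_x = rng.uniform(*config.beta_x_range, size=config.p)
    beta_w = rng.uniform(*config.beta_w_range, size=(config.p, config.k))
    pleio = rng.choice(config.k, size=config.n_pleiotropic, replace=False)
    delta = np.zeros(config.k)
    if config.sparsity_mode == DELTA_SPARSE:
        delta[pleio] = rng.uniform(*config.delta_range, size=config.n_pleiotropic)
    else:  # all delta nonzero; non-pleiotropic covariates have zero beta_W column
        delta = rng.uniform(*config.delta_range, size=config.k)
        delta[delta == 0.0] = 1e-12  # measure-zero guard
        off = np.setdiff1d(np.arange(config.k), pleio)
        beta_w[:, off] = 0.0
    return TrueParams(beta_x=beta_x, beta_w=beta_w, delta=delta, theta=config.theta)


def simulate_individual(
    config: SimulationConfig, params: TrueParams, rng: np.random.Generator
) -> IndividualData:
    """One sample of n individuals from the structural model."""
    n, p, k = config.n, config.p, config.k
    # Binomial(2, pi) as the sum of two Bernoulli draws: equivalent in
    # distribution and much faster at genome scale
    g = (
        (rng.random((n, p)) < config.pi).astype(float)
        + (rng.random((n, p)) < config.pi)
    )
    u = rng.standard_normal(n)
    x = g @ params.beta_x + config.gamma_x * u + rng.standard_normal(n)
    w = g @ params.beta_w + config.gamma_w * u[:, None] + rng.standard_normal((n, k))
    y = (
        params.theta * x
        + w @ params.delta
        + config.gamma_y * u
        + rng.standard_normal(n)
    )
    return IndividualData(genotypes=g, x=x, w=w, y=y, confounder=u)


def marginal_associations(g: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope and SE of the simple linear regression (with intercept) of each
    trait column in ``t`` on each genotype column of ``g``, vectorized over
    variants.

    Returns arrays of shape (p,) for a 1-D trait or (p, k) for an n x k
    trait matrix.  SEs use the usual residual-variance formula with n - 2
    degrees of freedom.
    """
    squeeze = t.ndim == 1
    t2 = t[:, None] if squeeze else t
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    tc = t2 - t2.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    if np.any(sxx == 0.0):
        raise ValueError("monomorphic variant: zero genotype variance")
    sxy = gc.T @ tc  # p x k
    slope = sxy / sxx[:, None]
    syy = np.einsum("ij,ij->j", tc, tc)
    rss = np.clip(syy[None, :] - slope**2 * sxx[:, None], 0.0, None)
    se = np.sqrt(rss / ((n - 2) * sxx[:, None]))
    if squeeze:
        return slope[:, 0], se[:, 0]
    return slope, se


def summarize(
    samples: list[IndividualData],
    assignment: tuple[int, int, int] = (0, 0, 1),
    variant_ids: list | None = None,
    covariate_names: list | None = None,
) -> SummaryData:
    """Per-variant summary statistics from one or more individual samples.

    ``assignment`` names the sample index supplying the exposure,
    covariate, and outcome associations respectively.  The default (0, 0, 1)
    is the two-sample design: exposure and covariate associations from the
    first sample, outcome associations and their standard errors from the
    second.  Passing the same index for every role yields a one-sample
    analysis (flagged in ``meta``).
    """
    if not samples:
        raise ValueError("at least one sample is required")
    ix, iw, iy = assignment
    for role, i in zip(("exposure", "covariate", "outcome"), assignment):
        if not 0 <= i < len(samples):
            raise ValueError(
                f"assignment routes the {role} associations to sample {i}, "
                f"but only {len(samples)} sample(s) were provided"
            )
    p = samples[0].genotypes.shape[1]
    k = samples[0].w.shape[1]
    beta_x, se_x = marginal_associations(samples[ix].genotypes, samples[ix].x)
    beta_w, se_w = marginal_associations(samples[iw].genotypes, samples[iw].w)
    beta_y, se_y = marginal_associations(samples[iy].genotypes, samples[iy].y)
    return SummaryData(
        variant_ids=variant_ids or [f"snp{j + 1}" for j in range(p)],
        beta_x=beta_x,
        beta_w=beta_w,
        beta_y=beta_y,
        se_y=se_y,
        covariate_names=covariate_names or [f"w{j + 1}" for j in range(k)],
        se_x=se_x,
        se_w=se_w,
        meta={"assignment": tuple(assignment), "one_sample": len(set(assignment)) == 1},
    )


def scenario_preset(
    which: int,
    theta: float,
    n_pleiotropic: int,
    sparsity_mode: str = DELTA_SPARSE,
    **overrides,
) -> SimulationConfig:
    """The two study-scale presets: p=10/k=8 (scenario 1) and p=80/k=70
    (scenario 2), with their effect-size ranges and n=20 000 per sample.

    The pleiotropic-covariate counts exercised at each scale are 1/2/4
    (scenario 1) and 7/21/35 (scenario 2); other values are permitted with
    a warning.
    """
    if which not in _SCENARIO_DIMS:
        raise ValueError("scenario must be 1 or 2")
    if n_pleiotropic not in _EXPECTED_PLEIO[which]:
        warnings.warn(
            f"n_pleiotropic={n_pleiotropic} is outside the usual set "
            f"{_EXPECTED_PLEIO[which]} for scenario {which}",
            UserWarning,
        )
    p, k = _SCENARIO_DIMS[which]
    bx, bw = _SCENARIO_RANGES[which]
    cfg = SimulationConfig(
        p=p,
        k=k,
        theta=theta,
        beta_x_range=bx,
        beta_w_range=bw,
        n_pleiotropic=n_pleiotropic,
        sparsity_mode=sparsity_mode,
    )
    return replace(cfg, **overrides) if overrides else cfg


def simulate_summary(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    params: TrueParams | None = None,
) -> tuple[SummaryData, TrueParams, SummaryData | None]:
    """Draw parameters (unless given), simulate ``config.n_samples``
    independent samples from one rng stream, and summarize.

    Returns ``(analysis, params, selection)`` where ``analysis`` is the
    two-sample summary (exposure/covariates from sample 1, outcome from
    sample 2) and ``selection`` is a one-sample summary built from the third
    sample when ``config.n_samples >= 3`` (else None).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    if params is None:
        params = draw_true_params(config, rng)
    samples = [simulate_individual(config, params, rng) for _ in range(config.n_samples)]
    if config.n_samples == 1:
        analysis = summarize(samples, assignment=(0, 0, 0))
    else:
        analysis = summarize(samples, assignment=(0, 0, 1))
    selection = None
    if config.n_samples >= 3:
        selection = summarize([samples[2]], assignment=(0, 0, 0))
    return analysis, params, selection
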