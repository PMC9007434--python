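"""Shared fixtures: small deterministic summary datasets."""

import numpy as np
import pytest

from mrpleio import SummaryData


def make_summary(
    p: int = 12,
    k: int = 3,
    seed: int = 0,
    theta: float = 0.2,
    delta: np.ndarray | None = None,
    noise: float = 0.05,
) -> SummaryData:
    """A random but reproducible summary dataset whose outcome associations
    follow beta_y = theta*beta_x + beta_w @ delta + noise."""
    rng = np.random.default_rng(seed)
    beta_x = rng.uniform(0.1, 0.4, p)
    beta_w = rng.uniform(-0.3, 0.4, (p, k))
    if delta is None:
        delta = np.zeros(k)
        delta[0] = 0.25
    se_y = rng.uniform(0.02, 0.1, p)
    beta_y = theta * beta_x + beta_w @ delta + noise * rng.standard_normal(p) * se_y
    return SummaryData(
        variant_ids=[f"rs{i}" for i in range(p)],
        beta_x=beta_x,
        beta_w=beta_w,
        beta_y=beta_y,
        se_y=se_y,
        covariate_names=[f"w{j}" for j in range(k)],
    )


@pytest.fixture
def toy_data() -> SummaryData:
    return make_summary()


@pytest.fixture
def summary_factory():
    return make_summary
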