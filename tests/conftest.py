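import numpy as np
import pandas as pd
import pytest

from mindsmci.simulate import (
    BINARY_COLUMNS,
    CONTINUOUS_COLUMNS,
    GeneratorConfig,
    generate_cohort,
    separated_config,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Separated 4-cluster cohort small enough for per-test model fits."""
    cfg = separated_config(n_subjects=600, seed=3)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def default_cohort_10k():
    """Default-config cohort for survival / causal checks."""
    cfg = GeneratorConfig(n_subjects=10000, seed=17)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def frozen_state():
    """A frozen mid-sized sampler state for conditional-update oracles."""
    rng = np.random.default_rng(7)
    n, q = 40, 2
    u = rng.standard_normal((n, q))
    U1 = np.column_stack([u, np.ones(n)])
    x = (rng.random(n) < 0.4).astype(float)
    y = 0.5 + u @ np.array([0.8, -0.3]) + rng.standard_normal(n) * 0.7
    omega = rng.gamma(2.0, 0.1, size=n) + 0.02
    return {"n": n, "q": q, "u": u, "U1": U1, "x": x, "y": y, "omega": omega}


def binary_block(cohort):
    return cohort[BINARY_COLUMNS]


def continuous_block(cohort):
    return cohort[CONTINUOUS_COLUMNS]
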