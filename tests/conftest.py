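import numpy as np
import pandas as pd
import pytest

from permcomp.synthetic_cohort import (
    DEFAULT_QPCR_TARGETS,
    PlatformSpec,
    SimulationConfig,
    simulate_cohort,
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A reduced cohort (fast to simulate and analyze) with the default
    composition and covariate structure."""
    defaults = dict(
        n_per_phenotype=(12, 12, 12),
        platforms=(PlatformSpec("sanger", 500.0),),
        qpcr_targets=DEFAULT_QPCR_TARGETS,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def null_cohort():
    """A default-size null cohort (no injected effects), all platforms."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_metadata():
    """Six subjects, one two-level factor and one covariate."""
    return pd.DataFrame(
        {
            "group": ["A", "A", "A", "B", "B", "B"],
            "x": [0.1, 0.5, 0.2, 0.9, 0.4, 0.7],
        },
        index=[f"s{i}" for i in range(6)],
    )
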