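import numpy as np
import pytest

from pdrcea import default_parameter_set
from pdrcea.parameters import AcuityChangeModel, LifeTable, ModelConfig


@pytest.fixture(scope="session")
def base_config():
    """The shipped base case (built once; treat as read-only)."""
    return default_parameter_set()


@pytest.fixture()
def config(base_config):
    """A mutable copy of the base case."""
    return base_config.copy()


@pytest.fixture()
def short_config(base_config):
    """Base case truncated to a 14-year horizon for cheap trace tests."""
    cfg = base_config.copy()
    cfg.horizon_age = 70.0
    return cfg


def zero_life_table() -> LifeTable:
    z = np.zeros(LifeTable.MAX_AGE + 1)
    return LifeTable(q_female=z, q_male=z)


def random_valid_config(rng: np.random.Generator, base: ModelConfig,
                        horizon_age: float = 70.0) -> ModelConfig:
    """A randomly perturbed but structurally valid configuration."""
    cfg = base.copy()
    cfg.psa_specs = {}  # perturbed values no longer match the spec means
    cfg.horizon_age = horizon_age
    raw = rng.dirichlet(np.ones(8))
    dist = raw / raw.sum()
    dist[-1] = 1.0 - dist[:-1].sum()  # exact sum under float arithmetic
    cfg.baseline_band_distribution = dist.tolist()
    cfg.prp_acuity_model = AcuityChangeModel(
        annual_mean=float(rng.uniform(-6.0, 4.0)),
        annual_sd=float(rng.uniform(1.0, 10.0)),
    )
    cfg.natural_history = AcuityChangeModel(
        annual_mean=float(rng.uniform(-4.0, 1.0)),
        annual_sd=float(rng.uniform(1.0, 8.0)),
    )
    cfg.mortality.hr_diabetes = float(rng.uniform(0.5, 3.0))
    cfg.mortality.male_fraction = float(rng.uniform(0.0, 1.0))
    cfg.fellow_eye.p_fellow_per_cycle = float(rng.uniform(0.0, 0.2))
    cfg.fellow_eye.p_both_at_baseline = float(rng.uniform(0.0, 0.5))
    cfg.discount_rate_annual = float(rng.uniform(0.0, 0.06))
    cfg.scenario.effect_trajectory = str(rng.choice(["continued", "stabilised"]))
    return cfg
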