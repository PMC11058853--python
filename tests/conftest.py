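import numpy as np
import pytest

from colonysim.agents import StrainParams
from colonysim.config_io import NutrientConfig, RunConfig
from colonysim.engine import InoculationSpec
from colonysim.environment import PlateGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def circle_geometry():
    return PlateGeometry(60, 60, "circular")


@pytest.fixture
def rect_geometry():
    return PlateGeometry(40, 50, "rectangular")


def small_run_config(
    n: int = 60,
    shape: str = "circular",
    n_steps: int = 96,
    strain: StrainParams | None = None,
    inoculations=None,
    **nutrient_kw,
) -> RunConfig:
    """A desk-scale single-strain plate used across the suite."""
    cfg = RunConfig(n_rows=n, n_cols=n, shape=shape, px_per_mm2=5.54)
    defaults = dict(init_top=3, init_deep=6, sigma_top=0.6, sigma_deep=1.2, flowrate=0.5)
    defaults.update(nutrient_kw)
    cfg.nutrient = NutrientConfig(**defaults)
    cfg.strains = {"wt": strain or StrainParams("wt", uptake_rate_g0=0.1)}
    cfg.inoculations = inoculations or [
        InoculationSpec((n / 2, n / 2), 3.0, 50, "wt", "c0")
    ]
    cfg.n_steps = n_steps
    return cfg
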