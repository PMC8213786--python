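import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from circanuc.model import DEFAULT_PARAMS, limit_cycle_metrics, simulate_clock
from circanuc.synth import GeneratorPreset, builtin_presets, generate_experiment


def make_quiet_preset(**overrides) -> GeneratorPreset:
    """DKI preset with all stochastic trace components switched off."""
    d = builtin_presets()["DKI-default"].to_dict()
    d.update(noise_sd=0.0, background_sd=0.0, trend_slope=0.0,
             spike_rate=0.0, division_rate=0.0, period_sd=0.0, phase_sd=0.0)
    for ch in d["channels"]:
        ch["peak_cv"] = 0.0
    d.update(overrides)
    return GeneratorPreset.from_dict(d)


@pytest.fixture(scope="session")
def default_trajectory():
    """Converged default-parameter orbit shared across tests (40 days)."""
    return simulate_clock(DEFAULT_PARAMS, 960.0)


@pytest.fixture(scope="session")
def default_metrics(default_trajectory):
    return limit_cycle_metrics(default_trajectory, transient=240.0)


@pytest.fixture(scope="session")
def dki_frames():
    """Synthetic double knock-in cohort (50 cells, fixed seed)."""
    return generate_experiment(builtin_presets()["DKI-default"], n_cells=50, seed=1)


@pytest.fixture()
def quiet_preset():
    return make_quiet_preset()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
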