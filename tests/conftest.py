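import numpy as np
import pytest

from ojipkit import (
    FluorescenceTransient,
    SyntheticScenario,
    compute_areas,
    compute_jip,
    default_time_grid_us,
    extract_steps,
)


def derive(transient, **kw):
    """steps, areas, jip record of one transient (shared helper)."""
    steps = extract_steps(transient)
    areas = compute_areas(transient, steps)
    return steps, areas, compute_jip(steps, areas, **kw)


@pytest.fixture(scope="session")
def dense_exp_transient():
    """F(t) = 500 + 2000(1 − e^(−t/0.5 ms)) on the instrument-like grid."""
    t_us = default_time_grid_us()
    F = 500.0 + 2000.0 * (1.0 - np.exp(-t_us / 500.0))
    return FluorescenceTransient(t_us, F, label="exp-0.5ms")


@pytest.fixture(scope="session")
def clamped_exp_transient():
    """Rise V(t) = 1 − e^(−t/2 ms) with the baseline clamped to 0 up to the
    20 µs origin sample, sampled to a 40 ms peak: the closed-form fixture
    for area and initial-slope checks (extracted F_O is exactly 0)."""
    t_us = default_time_grid_us(t_end_us=40_000.0)
    V = 1.0 - np.exp(-t_us / 2000.0)
    F = np.where(t_us <= 20.0, 0.0, V)
    return FluorescenceTransient(t_us, F, label="exp-2ms-clamped")


@pytest.fixture(scope="session")
def quiet_scenario():
    """Noise-free control scenario used across simulator-recovery tests."""
    return SyntheticScenario(noise_sd=0.0)
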