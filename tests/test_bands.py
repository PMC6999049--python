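import numpy as np
import pytest

from ojipkit import (
    FluorescenceTransient,
    SyntheticScenario,
    difference_kinetics,
    extract_steps,
    normalize_curves,
    simulate_ojip,
    wip_half_time,
)
from ojipkit.bands import NormalizedCurves


def curves_for(transient):
    return normalize_curves(transient, extract_steps(transient))


def make_wip_curves(t_ms, w_ip):
    """NormalizedCurves carrying only a W_IP trace (for half-time tests)."""
    t_us = np.asarray(t_ms, float) * 1e3
    z = np.zeros_like(t_us)
    steps = extract_steps(
        simulate_ojip(SyntheticScenario(noise_sd=0.0))
    )
    return NormalizedCurves(time=t_us, V_t=z, W_OK=z, W_OJ=z, W_OI=z,
                            W_IP=np.asarray(w_ip, float), steps=steps)


class TestNormalizeCurves:
    def test_landmark_endpoints(self, dense_exp_transient):
        c = curves_for(dense_exp_transient)
        t = c.time
        assert np.interp(2_000.0, t, c.W_OJ) == pytest.approx(1.0, abs=1e-9)
        assert np.interp(20.0, t, c.W_OJ) == pytest.approx(0.0, abs=1e-9)
        assert np.interp(30_000.0, t, c.W_OI) == pytest.approx(1.0, abs=1e-9)
        assert np.interp(300.0, t, c.W_OK) == pytest.approx(1.0, abs=1e-9)

    def test_vt_equals_woj_times_vj(self, dense_exp_transient):
        c = curves_for(dense_exp_transient)
        V_J = (c.steps.F_J - c.steps.F_O) / c.steps.F_V
        np.testing.assert_allclose(c.V_t, c.W_OJ * V_J, atol=1e-12)

    def test_flat_landmark_flags_only_that_curve(self):
        from ojipkit import default_time_grid_us

        t = default_time_grid_us()  # dense early grid brackets 300 µs
        F = np.where(t <= 310, 500.0, 500 + 2000 * (1 - np.exp(-(t - 310) / 2000.0)))
        tr = FluorescenceTransient(t, F)
        c = curves_for(tr)  # F_K == F_O: W_OK undefined
        assert "W_OK" in c.invalid
        assert "V_t" not in c.invalid and "W_OJ" not in c.invalid

    def test_woi_tail_restricted_to_ge_one(self, quiet_scenario):
        tr = simulate_ojip(quiet_scenario)
        t_ms, w = curves_for(tr).woi_tail()
        assert np.all(w >= 1.0)
        assert t_ms.min() >= 30.0 and t_ms.max() <= 530.0


class TestDifferenceKinetics:
    def test_identical_samples_vanish(self, dense_exp_transient):
        c = curves_for(dense_exp_transient)
        b = difference_kinetics(c, c)
        np.testing.assert_allclose(b.dV_t, 0.0, atol=1e-12)
        np.testing.assert_allclose(b.dW_OK, 0.0, atol=1e-12)
        assert b.J_peak == pytest.approx(0.0, abs=1e-12)

    def test_constructed_j_region_shift(self):
        # τ = 5 ms keeps the bumped region well below the peak, so F_O and
        # F_M (hence the V_t normalization) are identical in both samples
        t = np.linspace(10, 1e6, 4000)
        F = 500 + 2000 * (1 - np.exp(-t / 5000.0))
        control = FluorescenceTransient(t, F)
        bump = np.where((t >= 1000) & (t <= 3000), 0.1 * 2000, 0.0)
        treated = FluorescenceTransient(t, F + bump)
        b = difference_kinetics(curves_for(treated), curves_for(control))
        assert b.J_peak == pytest.approx(0.1, rel=0.05)
        assert 1000 <= b.J_peak_time <= 3000

    def test_disjoint_ranges_error(self):
        t1 = np.linspace(10, 1e4, 100)
        t2 = np.linspace(2e4, 1e6, 100)
        a = curves_for(FluorescenceTransient(t1, np.linspace(100, 200, 100)))
        c2 = NormalizedCurves(time=t2, V_t=np.zeros(100), W_OK=np.zeros(100),
                              W_OJ=np.zeros(100), W_OI=np.zeros(100),
                              W_IP=np.zeros(100), steps=a.steps)
        with pytest.raises(ValueError, match="overlap"):
            difference_kinetics(a, c2)

    def test_simulator_pair_j_band_dominates_l_band(self, quiet_scenario):
        control = simulate_ojip(quiet_scenario)
        treated = simulate_ojip(quiet_scenario.with_(B=0.5))
        b = difference_kinetics(curves_for(treated), curves_for(control))
        assert b.J_peak > 0.15  # raised J step is the dominant response
        assert abs(b.L_band) < 0.3 * b.J_peak  # L-band comparatively quiet

    def test_lower_connectivity_raises_l_band(self, quiet_scenario):
        control = curves_for(simulate_ojip(quiet_scenario))  # p = 0.25
        l_vals = []
        for p in (0.0, 0.25, 0.5):
            treated = curves_for(simulate_ojip(quiet_scenario.with_(p=p)))
            l_vals.append(difference_kinetics(treated, control).L_band)
        assert l_vals[0] > l_vals[1] > l_vals[2]


class TestWipHalfTime:
    def test_midpoint_interpolation(self):
        c = make_wip_curves([30.0, 50.0, 100.0], [0.4, 0.6, 1.0])
        assert wip_half_time(c) == pytest.approx(40.0)

    def test_exponential_closed_form(self):
        t = np.linspace(30, 530, 2001)
        w = 1 - np.exp(-(t - 30) / 100.0)
        assert wip_half_time(make_wip_curves(t, w)) == pytest.approx(
            30 + 100 * np.log(2), rel=1e-3
        )

    def test_no_crossing_flagged(self):
        t = np.linspace(30, 530, 100)
        assert np.isnan(wip_half_time(make_wip_curves(t, 0.3 + 0.001 * (t - 30) / 500)))

    def test_invariant_to_fluorescence_rescaling(self, quiet_scenario):
        tr = simulate_ojip(quiet_scenario)
        scaled = FluorescenceTransient(tr.time, 3.7 * tr.F)
        assert wip_half_time(curves_for(tr)) == pytest.approx(
            wip_half_time(curves_for(scaled)), abs=1e-9
        )
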