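import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ojipkit import (
    AreaValues,
    StepValues,
    compare_groups,
    compute_jip,
    compute_quench,
    relative_variable_fluorescence,
)
from ojipkit.induction import DegenerateTransientError


def make_steps(F_O, F_J, F_I, F_M, *, F_K=None, t_FM=300.0):
    F_K = F_K if F_K is not None else F_O + 0.15 * (F_M - F_O)
    return StepValues(
        F_O=F_O, F_L=F_O + 0.08 * (F_M - F_O), F_K=F_K, F_J=F_J, F_I=F_I,
        F_M=F_M, t_FM=t_FM, F_270=F_K,
    )


def make_areas(steps, M_0, *, S_m=25.0):
    V_J = (steps.F_J - steps.F_O) / steps.F_V
    return AreaValues(Area=S_m * steps.F_V, S_m=S_m, M_0=M_0, S_s=V_J / M_0)


class TestWorkedRecord:
    """Hand-evaluated record: F_O=500, F_J=1500, F_I=2100, F_M=2500, M_0=1."""

    steps = make_steps(500.0, 1500.0, 2100.0, 2500.0)
    res = compute_jip(steps, make_areas(steps, 1.0))

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("phi_Po", 0.8),
            ("V_J", 0.5),
            ("psi_Eo", 0.5),
            ("phi_Eo", 0.4),
            ("V_I", 0.8),
            ("delta_Ro", 0.4),
            ("phi_Ro", 0.16),
            ("gamma_RC", 0.4 / 1.4),
            ("PI_ABS", 1.6),
            ("PI_total", 1.6 * (0.4 / 0.6)),
        ],
    )
    def test_field(self, name, expected):
        assert getattr(self.res, name) == pytest.approx(expected, abs=1e-9)

    def test_rc_per_abs_is_point_four(self):
        assert self.res.RC_CS / self.res.ABS_CS == pytest.approx(0.4, abs=1e-12)


class TestBoundaries:
    def test_saturated_j_step(self):
        steps = make_steps(500.0, 2500.0, 2500.0, 2500.0)  # F_J = F_M
        res = compute_jip(steps, make_areas(steps, 1.0))
        assert res.saturated_J
        assert res.psi_Eo == 0.0
        assert res.PI_ABS == 0.0 and res.PI_total == 0.0
        assert math.isnan(res.delta_Ro)

    def test_yield_complementarity(self):
        steps = make_steps(625.0, 1500.0, 2100.0, 2500.0)  # F_O = 0.25 F_M
        res = compute_jip(steps, make_areas(steps, 1.0))
        assert res.phi_Po == pytest.approx(0.75, abs=1e-12)
        assert res.phi_Do == pytest.approx(0.25, abs=1e-12)
        assert res.phi_Po + res.phi_Do == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_steps_error(self):
        steps = make_steps(500.0, 500.0, 500.0, 500.0 + 1e-30)
        with pytest.raises((DegenerateTransientError, ZeroDivisionError)):
            compute_jip(make_steps(500.0, 500.0, 500.0, 500.0),
                        make_areas(steps, 1.0))


class TestRelativeVariableFluorescence:
    steps = make_steps(500.0, 1500.0, 2100.0, 2500.0)

    def test_midpoint(self):
        assert relative_variable_fluorescence(self.steps, 1500.0) == pytest.approx(0.5)

    def test_endpoints(self):
        assert relative_variable_fluorescence(self.steps, 500.0) == 0.0
        assert relative_variable_fluorescence(self.steps, 2500.0) == 1.0

    def test_typical_dark_adapted_ratio(self):
        steps = make_steps(0.29 * 2500, 1500.0, 2100.0, 2500.0)
        expected = (0.8 - 0.29) / (1 - 0.29)
        assert relative_variable_fluorescence(steps, 0.8 * 2500) == pytest.approx(expected)


@st.composite
def valid_steps_and_areas(draw):
    F_O = draw(st.floats(100.0, 2000.0))
    F_V = F_O * draw(st.floats(1.0, 5.0))
    V_J = draw(st.floats(0.05, 0.94))
    V_I = draw(st.floats(min(V_J + 0.01, 0.99), 0.99))
    M_0 = draw(st.floats(0.2, 3.0))
    steps = make_steps(F_O, F_O + V_J * F_V, F_O + V_I * F_V, F_O + F_V)
    return steps, make_areas(steps, M_0, S_m=draw(st.floats(5.0, 60.0)))


class TestAlgebraicIdentities:
    @given(valid_steps_and_areas())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_identities_hold_to_machine_precision(self, sa):
        steps, areas = sa
        r = compute_jip(steps, areas)
        assert abs(r.phi_Po + r.phi_Do - 1.0) < 1e-12
        assert abs(r.phi_Eo - r.phi_Po * r.psi_Eo) < 1e-12
        assert abs(r.phi_Ro - r.phi_Po * (1.0 - r.V_I)) < 1e-12
        assert abs(r.ABS_CS - (r.TR0_CS + r.DI0_CS)) < 1e-12 * max(1.0, r.ABS_CS)
        if math.isfinite(r.delta_Ro) and r.delta_Ro < 1.0:
            assert abs(r.PI_total - r.PI_ABS * r.delta_Ro / (1 - r.delta_Ro)) \
                < 1e-12 * max(1.0, abs(r.PI_total))
        assert 0.0 <= r.gamma_RC < 1.0

    def test_increasing_fj_monotonicity(self):
        base = dict(F_O=500.0, F_I=2100.0, F_M=2500.0)
        prev = None
        control = compute_jip(
            *(lambda s: (s, make_areas(s, 1.0)))(make_steps(500.0, 1200.0, 2100.0, 2500.0))
        )
        for F_J in (1300.0, 1500.0, 1700.0, 1900.0):
            s = make_steps(base["F_O"], F_J, base["F_I"], base["F_M"])
            r = compute_jip(s, make_areas(s, 1.0))
            rj = compare_groups([r], [control]).R_J
            if prev is not None:
                assert r.psi_Eo < prev[0]
                assert r.phi_Eo < prev[1]
                assert r.PI_ABS < prev[2]
                assert rj > prev[3]
            prev = (r.psi_Eo, r.phi_Eo, r.PI_ABS, rj)


class TestCompareGroups:
    steps_c = make_steps(500.0, 1300.0, 2100.0, 2500.0)  # V_J = 0.4
    steps_t = make_steps(500.0, 1900.0, 2100.0, 2500.0)  # V_J = 0.7
    res_c = compute_jip(steps_c, make_areas(steps_c, 1.0))
    res_t = compute_jip(steps_t, make_areas(steps_t, 1.0))

    def test_rj_from_group_mean_vj(self):
        comp = compare_groups([self.res_t], [self.res_c])
        assert comp.R_J == pytest.approx(0.5, abs=1e-12)

    def test_identity_comparison(self):
        comp = compare_groups([self.res_c], [self.res_c])
        assert comp.R_J == 0.0
        for name, v in comp.relative_params.items():
            if math.isfinite(v):
                assert v == pytest.approx(1.0, abs=1e-12), name

    def test_full_occupancy(self):
        steps = make_steps(500.0, 2500.0, 2500.0, 2500.0)
        res = compute_jip(steps, make_areas(steps, 1.0))
        assert compare_groups([res], [self.res_c]).R_J == pytest.approx(1.0)

    def test_negative_raw_clipped_but_kept(self):
        comp = compare_groups([self.res_c], [self.res_t])
        assert comp.R_J == 0.0
        assert comp.R_J_raw < 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups([], [self.res_c])


class TestQuench:
    def test_fv_over_fm(self):
        assert compute_quench(200, 1000, 400, 600).Fv_over_Fm == pytest.approx(0.8)

    def test_light_saturated_limit(self):
        q = compute_quench(200, 1000, 600, 600)
        assert q.Yield == 0.0 and q.qP == 0.0 and q.ETR == 0.0

    def test_worked_arithmetic(self):
        q = compute_quench(200, 1000, 400, 600, par=110, absorptance=0.84,
                           psii_fraction=0.5)
        assert q.Yield == pytest.approx(1 / 3)
        assert q.qP == pytest.approx(0.5)
        assert q.ETR == pytest.approx(110 * 0.84 * 0.5 / 3)

    def test_invalid_pulse_record(self):
        with pytest.raises(ValueError):
            compute_quench(200, 1000, 700, 600)
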