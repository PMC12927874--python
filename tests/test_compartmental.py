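"""Closed-form compartmental solutions against algebraic and numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from foalpk import (
    DoseEvent,
    Regimen,
    StructuralParams,
    concentration,
    free_concentration,
    mammillary_concentration,
    to_disposition_constants,
)

TABLE2 = StructuralParams(cl=17.43, v1=18.83, q=16.79, v2=22.12)


def ode_concentration(params, doses, t_grid):
    """Independent oracle: adaptive ODE integration of the 2-compartment system,
    restarted at every bolus."""
    k10, k12, k21 = params.cl / params.v1, params.q / params.v1, params.q / params.v2

    def rhs(t, a):
        return [-(k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    events = sorted(doses, key=lambda d: d.time)
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.zeros_like(t_grid)
    state = np.zeros(2)
    t_prev = 0.0
    segments = [(d.time, d.amount) for d in events] + [(t_grid.max() + 1e-9, 0.0)]
    for (t_d, amt) in segments:
        sel = (t_grid >= t_prev) & (t_grid < t_d)
        if np.any(sel) or t_d > t_prev:
            ts = t_grid[sel]
            sol = solve_ivp(
                rhs, (t_prev, t_d), state, t_eval=np.concatenate([ts, [t_d]]),
                rtol=1e-11, atol=1e-13, method="LSODA",
            )
            out[sel] = sol.y[0][: len(ts)]
            state = sol.y[:, -1]
        state = state.copy()
        state[0] += amt
        t_prev = t_d
    return out / params.v1


class TestDispositionConstants:
    def test_root_identities_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            cl, v1, q, v2 = np.exp(rng.uniform(np.log(0.1), np.log(100), 4))
            p = StructuralParams(cl, v1, q, v2)
            d = to_disposition_constants(p)
            assert d.alpha > d.beta > 0
            np.testing.assert_allclose(d.alpha * d.beta, d.k10 * d.k21, rtol=1e-12)
            np.testing.assert_allclose(d.alpha + d.beta, d.k10 + d.k12 + d.k21, rtol=1e-12)

    def test_table2_roots_match_eigendecomposition(self):
        d = to_disposition_constants(TABLE2)
        k = np.array(
            [
                [-(d.k10 + d.k12), d.k21],
                [d.k12, -d.k21],
            ]
        )
        eig = np.sort(np.linalg.eigvals(k))
        np.testing.assert_allclose(sorted([-d.alpha, -d.beta]), eig, rtol=1e-12)

    def test_one_compartment_degenerate(self):
        p = StructuralParams(cl=5.0, v1=10.0, q=0.0)
        d = to_disposition_constants(p)
        assert d.alpha == pytest.approx(0.5)
        t = np.linspace(0, 10, 50)
        c = concentration(p, [DoseEvent(0.0, 100.0)], t)
        np.testing.assert_allclose(c, 10.0 * np.exp(-0.5 * t), rtol=1e-12)

    def test_q_to_zero_limit_continuity(self):
        t = np.linspace(0, 12, 40)
        base = concentration(StructuralParams(5.0, 10.0, 0.0), [DoseEvent(0.0, 50.0)], t)
        near = concentration(StructuralParams(5.0, 10.0, 1e-9, 8.0), [DoseEvent(0.0, 50.0)], t)
        np.testing.assert_allclose(near, base, rtol=1e-6)

    @pytest.mark.parametrize("field,kwargs", [
        ("cl", dict(cl=-1.0, v1=1.0)),
        ("v1", dict(cl=1.0, v1=0.0)),
        ("v2", dict(cl=1.0, v1=1.0, q=1.0, v2=-2.0)),
    ])
    def test_invalid_parameters_name_the_field(self, field, kwargs):
        with pytest.raises(ValueError, match=field):
            StructuralParams(**kwargs)


class TestConcentration:
    def test_instantaneous_mixing_limit(self):
        # 20 mg/kg x 48.5 kg into V1 = 18.83 L
        c = concentration(TABLE2, [DoseEvent(0.0, 970.0)], np.array([0.0]))
        assert c[0] == pytest.approx(970.0 / 18.83, rel=1e-12)
        assert c[0] == pytest.approx(51.52, abs=0.01)

    def test_matches_ode_oracle_random_parameters(self):
        rng = np.random.default_rng(42)
        doses = [DoseEvent(0.0, 500.0), DoseEvent(6.0, 500.0), DoseEvent(12.0, 500.0)]
        t = np.linspace(0.0, 24.0, 121)
        worst = 0.0
        for _ in range(100):
            cl, v1, q, v2 = np.exp(rng.uniform(np.log(0.1), np.log(100), 4))
            p = StructuralParams(cl, v1, q, v2)
            closed = concentration(p, doses, t)
            ode = ode_concentration(p, doses, t)
            err = np.max(np.abs(closed - ode)) / np.max(np.abs(ode))
            worst = max(worst, err)
        assert worst < 1e-6

    @given(
        amt=st.floats(10.0, 5000.0),
        cl=st.floats(0.5, 50.0),
        v1=st.floats(1.0, 50.0),
        q=st.floats(0.5, 50.0),
        v2=st.floats(1.0, 80.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_superposition_and_dose_linearity(self, amt, cl, v1, q, v2):
        p = StructuralParams(cl, v1, q, v2)
        t = np.linspace(0, 30, 61)
        d1, d2 = DoseEvent(0.0, amt), DoseEvent(8.0, amt)
        both = concentration(p, [d1, d2], t)
        summed = concentration(p, [d1], t) + concentration(p, [d2], t)
        np.testing.assert_allclose(both, summed, rtol=1e-12, atol=1e-300)
        doubled = concentration(p, [DoseEvent(0.0, 2 * amt), DoseEvent(8.0, 2 * amt)], t)
        np.testing.assert_allclose(doubled, 2.0 * both, rtol=1e-12)

    def test_monotone_washout_after_last_dose(self):
        t = np.linspace(6.5, 48, 200)
        c = concentration(TABLE2, [DoseEvent(0.0, 970.0), DoseEvent(6.0, 970.0)], t)
        assert np.all(np.diff(c) < 0)

    def test_zero_before_first_dose_and_empty_doses(self):
        t = np.linspace(0, 10, 11)
        c = concentration(TABLE2, [DoseEvent(5.0, 100.0)], t)
        assert np.all(c[t < 5.0] == 0.0)
        assert np.all(concentration(TABLE2, [], t) == 0.0)

    def test_negative_time_grid_rejected(self):
        with pytest.raises(ValueError, match="t_grid"):
            concentration(TABLE2, [DoseEvent(0.0, 1.0)], np.array([-1.0, 0.0]))


class TestFreeConcentration:
    def test_protein_binding_15pct(self):
        np.testing.assert_allclose(free_concentration(np.array([100.0]), 0.85), [85.0])

    def test_identity_and_zero(self):
        x = np.array([0.0, 3.0, 7.0])
        np.testing.assert_array_equal(free_concentration(x, 1.0), x)
        assert free_concentration(np.array([0.0]), 0.85)[0] == 0.0

    @pytest.mark.parametrize("fu", [0.0, -0.1, 1.5])
    def test_invalid_fu_rejected(self, fu):
        with pytest.raises(ValueError, match="fu"):
            free_concentration(np.array([1.0]), fu)


class TestMammillary:
    def test_two_compartment_agrees_with_closed_form(self):
        t = np.linspace(0, 24, 49)
        doses = [DoseEvent(0.0, 970.0), DoseEvent(6.0, 970.0)]
        closed = concentration(TABLE2, doses, t)
        mat = mammillary_concentration(17.43, 18.83, [(16.79, 22.12)], doses, t)
        np.testing.assert_allclose(mat, closed, rtol=1e-9)

    def test_three_compartment_against_ode(self):
        cl, v1 = 10.0, 15.0
        periph = [(8.0, 20.0), (2.0, 40.0)]
        doses = [DoseEvent(0.0, 600.0)]
        t = np.linspace(0, 24, 49)

        def rhs(_, a):
            out = np.zeros(3)
            out[0] = -cl / v1 * a[0]
            for i, (q, v) in enumerate(periph, start=1):
                out[0] += -q / v1 * a[0] + q / v * a[i]
                out[i] = q / v1 * a[0] - q / v * a[i]
            return out

        sol = solve_ivp(rhs, (0, 24), [600.0, 0, 0], t_eval=t, rtol=1e-11, atol=1e-12)
        ours = mammillary_concentration(cl, v1, periph, doses, t)
        np.testing.assert_allclose(ours, sol.y[0] / v1, rtol=1e-6, atol=1e-10)


class TestRegimen:
    def test_dose_events_and_daily_dose(self):
        r = Regimen(20.0, 6.0, horizon=48.0)
        ev = r.dose_events(48.5)
        assert len(ev) == 8
        assert ev[0].time == 0.0 and ev[-1].time == 42.0
        assert all(e.amount == pytest.approx(970.0) for e in ev)
        assert r.daily_dose == pytest.approx(80.0)
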