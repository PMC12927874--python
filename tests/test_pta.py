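"""fT>MIC computation and Monte Carlo PTA engine properties."""

import math

import numpy as np
import pytest

from foalpk import (
    DoseEvent,
    PKPDTarget,
    PopulationScenario,
    Regimen,
    StructuralParams,
    age_scenario_population,
    ft_above_threshold,
    pta_report,
    simulate_pta,
)
from foalpk.compartmental import concentration, free_concentration
from foalpk.pta import ConcentrationProfile


def _profile(params, doses, fu=0.85, step=0.02, horizon=48.0):
    t = np.arange(0.0, horizon + step / 2, step)
    total = concentration(params, doses, t)
    return ConcentrationProfile(t, total, free_concentration(total, fu))


class TestFtAboveThreshold:
    def test_threshold_below_and_above_profile(self):
        p = StructuralParams(17.43, 18.83, 16.79, 22.12)
        doses = Regimen(20.0, 6.0).dose_events(48.5)
        prof = _profile(p, doses)
        assert ft_above_threshold(prof, 1e-6) == pytest.approx(1.0, abs=1e-6)
        assert ft_above_threshold(prof, 1e6) == 0.0
        assert ft_above_threshold(prof, 0.0) == 1.0  # convention for MIC <= 0

    def test_one_compartment_closed_form_oracle(self):
        """Single bolus, mono-exponential decay: time above MIC is
        ln(C0_free/MIC)/k; the numerical result matches to 1e-4."""
        cl, v1, fu = 6.0, 15.0, 0.85
        k = cl / v1
        dose = 900.0
        mic = 2.0
        c0_free = fu * dose / v1
        t_above = math.log(c0_free / mic) / k
        expected = min(t_above / 48.0, 1.0)
        p = StructuralParams(cl, v1)
        doses = [DoseEvent(0.0, dose)]
        got_grid = ft_above_threshold(_profile(p, doses, fu=fu), mic)
        assert got_grid == pytest.approx(expected, abs=1e-4)
        # exact root-bracketing path on the free-scale threshold
        got_exact = ft_above_threshold(None, mic / fu, params_and_doses=(p, doses))
        assert got_exact == pytest.approx(expected, abs=1e-6)

    def test_grid_and_exact_paths_agree_multidose(self):
        p = StructuralParams(17.43, 18.83, 16.79, 22.12)
        doses = Regimen(20.0, 6.0).dose_events(48.5)
        mic = 0.5
        grid = ft_above_threshold(_profile(p, doses), mic)
        exact = ft_above_threshold(None, mic / 0.85, params_and_doses=(p, doses))
        assert grid == pytest.approx(exact, abs=1e-3)


class TestAgeScenario:
    def test_median_and_one_sd_range(self):
        ages = age_scenario_population(10.0, 0.5, 100_000, np.random.default_rng(1))
        assert np.median(ages) == pytest.approx(10.0, rel=0.02)
        lo, hi = np.quantile(ages, [0.1587, 0.8413])  # +-1 log-SD
        assert lo == pytest.approx(6.07, rel=0.03)
        assert hi == pytest.approx(16.49, rel=0.03)

    def test_zero_log_sd_degenerates_to_median(self):
        ages = age_scenario_population(120.0, 0.0, 100, np.random.default_rng(2))
        np.testing.assert_allclose(ages, 120.0)

    def test_invalid_median_rejected(self):
        with pytest.raises(ValueError):
            age_scenario_population(-1.0, 0.5, 10, np.random.default_rng(0))


@pytest.fixture(scope="module")
def grid_result(table2_model):
    regs = [Regimen(d, i) for d in (15.0, 40.0) for i in (4.0, 8.0)]
    mics = (0.06, 0.5, 2.0)
    targets = (PKPDTarget(0.5, 1.0), PKPDTarget(1.0, 1.0))
    scen = PopulationScenario(n_subjects=500)
    return simulate_pta(table2_model, regs, mics, targets, scen, rng=7)


class TestSimulatePta:
    def test_pta_bounded_and_seeded_reproducible(self, table2_model, grid_result):
        assert grid_result.table["pta"].between(0, 100).all()
        again = simulate_pta(
            table2_model,
            [Regimen(d, i) for d in (15.0, 40.0) for i in (4.0, 8.0)],
            (0.06, 0.5, 2.0),
            (PKPDTarget(0.5, 1.0), PKPDTarget(1.0, 1.0)),
            PopulationScenario(n_subjects=500),
            rng=7,
        )
        np.testing.assert_array_equal(again.table["pta"], grid_result.table["pta"])

    def test_monotone_in_mic_dose_interval(self, grid_result):
        t = grid_result.table
        tol = 0.5  # allow 1-subject Monte Carlo wobble at n=500
        for (_, _, _), g in t.groupby(["dose_per_kg", "interval", "target"]):
            p = g.sort_values("mic")["pta"].to_numpy()
            assert np.all(np.diff(p) <= tol)
        for (_, _, _), g in t.groupby(["interval", "mic", "target"]):
            p = g.sort_values("dose_per_kg")["pta"].to_numpy()
            assert np.all(np.diff(p) >= -tol)
        for (_, _, _), g in t.groupby(["dose_per_kg", "mic", "target"]):
            p = g.sort_values("interval")["pta"].to_numpy()
            assert np.all(np.diff(p) <= tol)

    def test_stricter_target_never_easier(self, grid_result):
        t = grid_result.table
        p50 = t[t["target"] == "50% fT > 1xMIC"].set_index(
            ["dose_per_kg", "interval", "mic"])["pta"]
        p100 = t[t["target"] == "100% fT > 1xMIC"].set_index(
            ["dose_per_kg", "interval", "mic"])["pta"]
        assert (p100 <= p50 + 1e-9).all()

    def test_full_binding_dominates(self, table2_model):
        regs = [Regimen(20.0, 6.0)]
        mics = (0.5, 2.0)
        targets = (PKPDTarget(0.5, 1.0),)
        lo = simulate_pta(table2_model, regs, mics, targets,
                          PopulationScenario(n_subjects=400, fu=0.85), rng=3)
        hi = simulate_pta(table2_model, regs, mics, targets,
                          PopulationScenario(n_subjects=400, fu=1.0), rng=3)
        assert (hi.table["pta"].to_numpy() >= lo.table["pta"].to_numpy()).all()

    def test_tiny_mic_reaches_full_attainment(self, table2_model):
        res = simulate_pta(table2_model, [Regimen(15.0, 8.0)], (0.016,),
                           (PKPDTarget(0.5, 1.0),),
                           PopulationScenario(n_subjects=400), rng=4)
        assert res.table["pta"].iloc[0] >= 99.0

    def test_empty_grids_rejected(self, table2_model):
        with pytest.raises(ValueError):
            simulate_pta(table2_model, [], (0.5,), (PKPDTarget(0.5),), rng=0)


class TestReport:
    def test_recommendations_monotone_and_flagging(self, table2_model):
        regs = [Regimen(d, i) for d in (15.0, 20.0, 40.0) for i in (4.0, 6.0, 8.0)]
        res = simulate_pta(table2_model, regs, (0.06, 0.5, 2.0, 8.0),
                           (PKPDTarget(0.5, 1.0),),
                           PopulationScenario(n_subjects=500), rng=9)
        rep = pta_report(res)
        assert set(rep.columns) >= {"mic", "recommendation", "switch_antimicrobial"}
        # exhaustion at very high MIC -> explicit switch flag
        assert bool(rep.loc[rep["mic"] == 8.0, "switch_antimicrobial"].iloc[0])
        # intensity (daily dose of the recommended regimen) non-decreasing in MIC
        daily = []
        for _, row in rep[~rep["switch_antimicrobial"]].sort_values("mic").iterrows():
            dose, interval = row["recommendation"].split(" mg/kg q")
            daily.append(float(dose) * 24.0 / float(interval.rstrip("h")))
        assert all(b >= a - 1e-9 for a, b in zip(daily, daily[1:]))
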