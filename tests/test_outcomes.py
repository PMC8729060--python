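"""Outcome integration: utility trajectories, discounting closed forms,
paired aggregation, horizons."""

import copy
import math

import numpy as np
import pytest

import endosim as es
from endosim.outcomes import (LifeHistory, compute_outcomes, utility_trajectory,
                              discounted_time, SimulationResult)
from endosim.adverse_events import AdverseEventInstance


def _flat_utilities(cfg, value=1.0, stage_value=None):
    cfg.utilities.age_band = {b: value for b in cfg.utilities.age_band}
    cfg.utilities.stage = {s: (stage_value if stage_value is not None else value)
                           for s in cfg.utilities.stage}


class TestClosedForms:
    def test_unit_utility_no_discounting(self, cfg):
        _flat_utilities(cfg)
        cfg.discount_rate = 0.0
        h = LifeHistory(age_dx=50.0, stage="1", arm="five_year",
                        bc_death_time=None, oc_death_age=60.0)
        rec = compute_outcomes(h, cfg)
        assert rec.ly == rec.qaly == pytest.approx(10.0)
        assert rec.ly_disc == rec.qaly_disc == pytest.approx(10.0)

    def test_discounted_one_year(self, cfg):
        _flat_utilities(cfg)
        h = LifeHistory(50.0, "1", "five_year", None, 51.0)
        rec = compute_outcomes(h, cfg)
        assert rec.ly_disc == pytest.approx((1 - math.exp(-0.03)) / 0.03, abs=1e-12)
        assert rec.ly_disc == pytest.approx(0.98515, abs=1e-4)

    def test_constant_utility_forty_years(self, cfg):
        u0 = 0.7
        _flat_utilities(cfg, value=1.0, stage_value=u0)
        h = LifeHistory(50.0, "1", "five_year", None, 90.0)
        rec = compute_outcomes(h, cfg)
        expect = u0 * (1 - math.exp(-1.2)) / 0.03
        assert rec.qaly_disc == pytest.approx(expect, abs=1e-10)
        assert expect / u0 == pytest.approx(23.294, abs=1e-3)

    def test_annual_step_discounting_matches_yearly_sum(self, cfg):
        r = 0.03
        t = 7.4
        expect = sum((1 + r) ** (-j) for j in range(7)) + (1 + r) ** (-7) * 0.4
        assert float(discounted_time(t, r, "annual")) == pytest.approx(expect, abs=1e-12)
        assert float(discounted_time(t, 0.0, "annual")) == t


class TestUtilityTrajectory:
    def test_age_and_stage_product_until_band_change(self, default_cfg):
        h = LifeHistory(55.0, "2a", "five_year", None, 75.0)
        bp, vals = utility_trajectory(h, default_cfg)
        assert bp[0] == 0.0 and bp[1] == pytest.approx(5.0)   # turns 60
        assert vals[0] == pytest.approx(0.837 * 0.85, abs=1e-12)
        assert vals[1] == pytest.approx(0.811 * 0.85, abs=1e-12)

    def test_active_event_multiplies(self, default_cfg):
        h = LifeHistory(55.0, "2a", "five_year", None, 75.0,
                        events=[AdverseEventInstance("pulmonary_embolus", 3.0, 3.75, 0.65)])
        bp, vals = utility_trajectory(h, default_cfg)
        i = np.searchsorted(bp, 3.0)
        assert bp[i] == 3.0
        assert vals[i] == pytest.approx(0.837 * 0.85 * 0.65, abs=1e-12)

    def test_all_unit_utilities_give_unit_trajectory(self, cfg):
        _flat_utilities(cfg)
        h = LifeHistory(40.0, "1", "five_year", 12.0, 70.0)
        _, vals = utility_trajectory(h, cfg)
        assert np.all(vals == 1.0)


class TestLifeHistorySemantics:
    def test_other_cause_death_first(self):
        h = LifeHistory(50.0, "1", "five_year", bc_death_time=10.0, oc_death_age=58.0)
        assert h.cause == "other"
        assert h.realized_death_age == 58.0

    def test_bc_death_first(self):
        h = LifeHistory(50.0, "1", "five_year", bc_death_time=6.0, oc_death_age=80.0)
        assert h.cause == "breast_cancer"
        assert h.realized_death_age == 56.0


class TestAggregation:
    def test_identical_arms_give_zero_difference_and_zero_se(self):
        res = SimulationResult()
        x = {m: np.array([1.0, 2.0, 3.0]) for m in
             ("bc_death", "ly", "ly_disc", "qaly", "qaly_disc")}
        res.add("25-49", "all", {"five_year": x, "ten_year": x})
        assert res.diff("25-49", "all", "qaly_disc") == 0.0
        assert res.se_diff("25-49", "all", "qaly_disc") == 0.0

    def test_paired_se_not_larger_than_unpaired(self, cfg, model):
        cfg.cohort.age_range = (25.0, 49.0)
        cfg.n_women = 50_000
        res = es.run_simulation(cfg, model)
        paired = res.se_diff("25-49", "all", "qaly_disc")
        unpaired = math.hypot(res.se("25-49", "all", "five_year", "qaly_disc"),
                              res.se("25-49", "all", "ten_year", "qaly_disc"))
        assert paired <= unpaired


@pytest.fixture(scope="module")
def run(model):
    c = es.default_scenario()
    c.n_women = 60_000
    return es.run_simulation(c, model, collect_arrays=True)


class TestRunInvariants:

    def test_qaly_bounded_by_ly_and_discounting_contracts(self, run):
        _, raw = run
        for arm in ("five_year", "ten_year"):
            a = raw[arm]
            assert np.all(a["qaly"] <= a["ly"] + 1e-9)
            assert np.all(a["ly_disc"] <= a["ly"] + 1e-9)
            assert np.all(a["qaly_disc"] <= a["qaly"] + 1e-9)
            assert np.all(a["qaly_disc"] <= a["ly_disc"] + 1e-9)
            assert np.all(a["ly"] >= 0)

    def test_no_bc_death_after_25_years(self, run):
        _, raw = run
        for arm in ("five_year", "ten_year"):
            t = raw[arm]["t_bc"]
            assert np.all(t[np.isfinite(t)] <= 25.0 + 1e-12)

    def test_zero_rate_discounting_is_identity(self, model):
        c = es.default_scenario()
        c.n_women = 20_000
        c.discount_rate = 0.0
        _, raw = es.run_simulation(c, model, collect_arrays=True)
        for arm in ("five_year", "ten_year"):
            assert np.allclose(raw[arm]["ly"], raw[arm]["ly_disc"])
            assert np.allclose(raw[arm]["qaly"], raw[arm]["qaly_disc"])

    def test_identical_multipliers_give_identical_histories(self, model):
        c = es.default_scenario()
        c.n_women = 20_000
        for h in c.hazard_ratios:
            h.hr10 = h.hr5
        for e in c.adverse_events:
            if e.name in ("osteoporosis", "grade12"):
                e.prob = {k: (0.0, 0.0) for k in e.prob}
            else:
                e.prob = {k: (p5, p5) for k, (p5, _) in e.prob.items()}
        _, raw = es.run_simulation(c, model, collect_arrays=True)
        for m in ("bc_death", "ly", "qaly", "qaly_disc", "t_bc"):
            assert np.array_equal(raw["five_year"][m], raw["ten_year"][m])

    def test_15y_horizon_clips_and_mortality_difference_smaller(self, model):
        c = es.default_scenario()
        c.cohort.age_range = (25.0, 49.0)
        c.n_women = 150_000
        res_life = es.run_simulation(c, model, mortality_only=True)
        c15 = copy.deepcopy(c)
        c15.horizon = "15y"
        _, raw15 = es.run_simulation(c15, model, mortality_only=True,
                                     collect_arrays=True)
        for arm in ("five_year", "ten_year"):
            assert np.all(raw15[arm]["ly"] <= 15.0 + 1e-12)
        res15 = es.run_simulation(c15, model, mortality_only=True)
        d15 = -res15.diff("25-49", "all", "bc_death")
        dlife = -res_life.diff("25-49", "all", "bc_death")
        assert 0 < d15 <= dlife

    def test_node_positive_qaly_gain_exceeds_node_negative(self, model):
        c = es.default_scenario()
        c.cohort.age_range = (25.0, 49.0)
        c.n_women = 400_000
        res = es.run_simulation(c, model)
        gain_pos = res.diff("25-49", "positive", "qaly_disc")
        gain_neg = res.diff("25-49", "negative", "qaly_disc")
        se = math.hypot(res.se_diff("25-49", "positive", "qaly_disc"),
                        res.se_diff("25-49", "negative", "qaly_disc"))
        assert gain_pos - gain_neg > -3 * se
        assert gain_pos > gain_neg
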