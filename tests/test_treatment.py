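"""Regimen assignment, piecewise hazard multipliers, completion scaling,
and the monotone CRN coupling of breast-cancer death times."""

import numpy as np
import pytest

import endosim as es
from endosim.natural_history import TruncatedWeibull, closed_form_lambda
from endosim.treatment import (assign_regimen, tail_multiplier, effective_hrs,
                               arm_multipliers, evaluate_bc_death)
from endosim.adverse_events import effective_probabilities


class TestAssignRegimen:
    def test_young_node_positive_gets_tamoxifen_os_with_chemo(self, default_cfg):
        a = assign_regimen(45.0, "2b", default_cfg)
        assert a.regimen == "tamoxifen_os" and a.chemo
        assert (a.hr_pair.hr5, a.hr_pair.hr10) == (0.66, 0.50)

    def test_older_stage1_gets_ai_without_chemo(self, default_cfg):
        a = assign_regimen(62.0, "1", default_cfg)
        assert a.regimen == "aromatase_inhibitor" and not a.chemo
        assert (a.hr_pair.hr5, a.hr_pair.hr10) == (0.55, 0.54)

    def test_young_node_negative_stage2a_gets_plain_tamoxifen(self, default_cfg):
        a = assign_regimen(45.0, "2a", default_cfg)
        assert a.regimen == "tamoxifen" and a.chemo

    def test_young_stage1_hr(self, default_cfg):
        a = assign_regimen(30.0, "1", default_cfg)
        assert a.regimen == "tamoxifen"
        assert (a.hr_pair.hr5, a.hr_pair.hr10) == (0.70, 0.54)

    def test_age_outside_range_raises(self, default_cfg):
        with pytest.raises(ValueError):
            assign_regimen(20.0, "1", default_cfg)


class TestTailMultiplier:
    def test_arithmetic_example(self):
        # hr5=0.70, hr10=0.54, Lambda5 = 0.3*Lambda25
        m = tail_multiplier(0.70, 0.54, 0.3, 1.0)
        assert m == pytest.approx((0.54 - 0.21) / 0.7, abs=1e-12)

    def test_equal_hrs_collapse_to_hr5(self):
        assert tail_multiplier(0.6, 0.6, 0.3, 1.0) == pytest.approx(0.6)

    def test_all_hazard_in_tail(self):
        assert tail_multiplier(0.7, 0.54, 0.0, 1.0) == pytest.approx(0.54)

    def test_infeasible_inputs_raise(self):
        with pytest.raises(ValueError):
            tail_multiplier(0.7, 0.54, 0.9, 1.0)   # m_tail would be negative
        with pytest.raises(ValueError):
            tail_multiplier(0.7, 0.54, 1.0, 1.0)   # Lambda25 == Lambda5


class TestCompletionScaling:
    def test_full_completion_is_identity(self):
        h5, h10 = effective_hrs(0.70, 0.54, (1.0, 1.0))
        assert h5 == 0.70 and h10 == 0.54

    def test_published_scaling_example(self):
        # 70% completion on HR 0.54 -> 1 - 0.7*0.46 = 0.678
        _, h10 = effective_hrs(0.54, 0.54, (0.7, 0.7))
        assert h10 == pytest.approx(0.678, abs=1e-12)

    def test_ae_probabilities_scale_with_completion(self, cfg):
        cfg.completion = (0.7, 0.7)
        probs = effective_probabilities(cfg, "five_year")
        total = 100 * sum(probs[e.name][0] for e in cfg.adverse_events
                          if e.grade_class == "grade34")
        assert total == pytest.approx(0.7 * 23.18, abs=1e-9)

    def test_hr_eff_monotone_and_continuous_in_c(self):
        cs = np.linspace(1e-6, 1.0, 50)
        vals = [effective_hrs(0.54, 0.54, (c, c))[1] for c in cs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(1.0, abs=1e-5)   # c -> 0+ gives hr -> 1

    def test_nonpositive_fraction_raises(self):
        with pytest.raises(ValueError):
            effective_hrs(0.7, 0.54, (0.0, 1.0))


class TestBCDeathEvaluation:
    shape = TruncatedWeibull(1.0, 7.0)

    def test_survivor_when_latent_exceeds_total_hazard(self):
        t = evaluate_bc_death(np.array([0.5]), 1.0, 1.0, 0.2, self.shape)
        assert np.isinf(t[0])

    def test_crn_identity_for_identical_multipliers(self):
        E = np.random.default_rng(1).exponential(size=1000)
        t1 = evaluate_bc_death(E, 0.7, 0.7, 0.18, self.shape)
        t2 = evaluate_bc_death(E, 0.7, 0.7, 0.18, self.shape)
        assert np.array_equal(t1, t2)

    def test_monotone_coupling_lower_multiplier_never_earlier(self):
        E = np.random.default_rng(2).exponential(size=20_000)
        m5e, m5t = arm_multipliers(0.70, 0.54, float(self.shape.cdf(5.0)), "five_year")
        m10e, m10t = arm_multipliers(0.70, 0.54, float(self.shape.cdf(5.0)), "ten_year")
        t5 = evaluate_bc_death(E, m5e, m5t, 0.25, self.shape)
        t10 = evaluate_bc_death(E, m10e, m10t, 0.25, self.shape)
        assert np.all(t10 >= t5)
        assert np.all(t5[np.isfinite(t5)] <= 25.0)

    def test_power_identity_without_competing_mortality(self):
        """Closed-form oracle: with a single stratum and no competing
        deaths, p10 = 1 - (1-p5)^(hr10/hr5)."""
        hr5, hr10, p5_target = 0.70, 0.54, 0.1191
        lam = closed_form_lambda(p5_target, hr5)
        n = 1_000_000
        E = np.random.default_rng(3).exponential(size=n)
        F5 = float(self.shape.cdf(5.0))
        t5 = evaluate_bc_death(E, *arm_multipliers(hr5, hr10, F5, "five_year"),
                               lam, self.shape)
        t10 = evaluate_bc_death(E, *arm_multipliers(hr5, hr10, F5, "ten_year"),
                                lam, self.shape)
        p5 = np.mean(np.isfinite(t5))
        p10 = np.mean(np.isfinite(t10))
        oracle = es.no_competing_p10(p5_target, hr5, hr10)
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert p5 == pytest.approx(p5_target, abs=3 * np.sqrt(p5_target * (1 - p5_target) / n))
        assert abs(p10 - oracle) <= 3 * se

    def test_no_between_arm_difference_in_first_five_years(self, cfg, model):
        cfg.n_women = 100_000
        _, raw = es.run_simulation(cfg, model, mortality_only=True,
                                   collect_arrays=True)
        t5, t10 = raw["five_year"]["t_bc"], raw["ten_year"]["t_bc"]
        early5, early10 = t5 <= 5.0, t10 <= 5.0
        assert np.array_equal(early5, early10)
        assert np.array_equal(t5[early5], t10[early10])
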