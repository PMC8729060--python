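"""Adverse events: sampling frequencies, CRN coupling across arms, and
utility-decrement segment semantics."""

import numpy as np
import pytest

import endosim as es
from endosim.adverse_events import (sample_event_arrays, sample_adverse_events,
                                    event_utility_segments, AdverseEventInstance,
                                    GRADE34_EVENTS)

TABLE_TAM_5Y = {"stroke": 0.0185, "pulmonary_embolus": 0.0303, "new_cardiac": 0.0253,
                "fracture": 0.0109, "endometrial_cancer": 0.0098,
                "osteoporosis": 0.1370, "grade12": 0.7167}


def test_empirical_frequencies_match_inputs_within_three_ses(cfg):
    n = 100_000
    codes = np.zeros(n, dtype=np.int8)    # all tamoxifen
    occ, _ = sample_event_arrays(cfg, "five_year", codes, 0, n)
    for name, p in TABLE_TAM_5Y.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(occ[name]) - p) <= 3 * se, name


def test_ten_year_counts_dominate_where_probability_increases(cfg):
    n = 50_000
    codes = np.zeros(n, dtype=np.int8)
    occ5, _ = sample_event_arrays(cfg, "five_year", codes, 0, n)
    occ10, _ = sample_event_arrays(cfg, "ten_year", codes, 0, n)
    # tamoxifen: stroke/PE/endometrial rise with duration; cardiac and
    # osteoporosis fall -- orderings hold woman-by-woman under shared draws
    for name in ("stroke", "pulmonary_embolus", "endometrial_cancer", "grade12"):
        assert np.all(occ10[name] >= occ5[name]), name
    for name in ("new_cardiac", "osteoporosis"):
        assert np.all(occ10[name] <= occ5[name]), name


def test_first_five_years_shared_onsets(cfg):
    n = 50_000
    codes = np.full(n, 2, dtype=np.int8)  # aromatase inhibitor
    occ5, on5 = sample_event_arrays(cfg, "five_year", codes, 0, n)
    occ10, on10 = sample_event_arrays(cfg, "ten_year", codes, 0, n)
    for name in GRADE34_EVENTS:
        both = occ5[name] & occ10[name]
        assert np.array_equal(on5[name][both], on10[name][both]), name
        only10 = occ10[name] & ~occ5[name]
        assert np.all(on10[name][only10] > 5.0), name
        assert np.all(on5[name][occ5[name]] <= 5.0), name
        assert np.all(on10[name][occ10[name]] <= 10.0), name


def test_five_year_events_reproducible_regardless_of_other_arm(cfg):
    codes = np.zeros(1000, dtype=np.int8)
    occ_a, on_a = sample_event_arrays(cfg, "five_year", codes, 0, 1000)
    _ = sample_event_arrays(cfg, "ten_year", codes, 0, 1000)
    occ_b, on_b = sample_event_arrays(cfg, "five_year", codes, 0, 1000)
    for name in occ_a:
        assert np.array_equal(occ_a[name], occ_b[name])
        assert np.array_equal(on_a[name], on_b[name])


def test_zero_probabilities_give_empty_event_list(cfg):
    for e in cfg.adverse_events:
        e.prob = {k: (0.0, 0.0) for k in e.prob}
    assert sample_adverse_events(cfg, "five_year", "tamoxifen", 0) == []


def test_affected_woman_gets_exactly_two_grade12_instances(cfg):
    # force the pooled grade 1-2 event on
    cfg.event("grade12").prob = {k: (1.0, 1.0) for k in cfg.event("grade12").prob}
    for e in cfg.adverse_events:
        if e.name != "grade12":
            e.prob = {k: (0.0, 0.0) for k in e.prob}
    events = sample_adverse_events(cfg, "five_year", "tamoxifen", 0)
    assert len(events) == 2
    assert events[0].onset == 0.0 and events[1].onset == 2.5
    assert events[0].utility_initial == 0.9 and events[1].utility_initial == 0.85
    events10 = sample_adverse_events(cfg, "ten_year", "tamoxifen", 0)
    assert events10[1].onset == 5.0


class TestUtilitySegments:
    def test_pulmonary_embolus_nine_month_span(self, default_cfg):
        spec = default_cfg.event("pulmonary_embolus")
        inst = AdverseEventInstance("pulmonary_embolus", 3.0, 3.75, 0.65)
        assert event_utility_segments(inst, spec, 40.0) == [(3.0, 3.75, 0.65)]

    def test_new_cardiac_lifetime_span(self, default_cfg):
        spec = default_cfg.event("new_cardiac")
        inst = AdverseEventInstance("new_cardiac", 2.0, np.inf, 0.8)
        assert event_utility_segments(inst, spec, 40.0) == [(2.0, 40.0, 0.8)]

    def test_stroke_acute_then_continuing(self, default_cfg):
        spec = default_cfg.event("stroke")
        inst = AdverseEventInstance("stroke", 4.0, np.inf, 0.7, 0.85)
        assert event_utility_segments(inst, spec, 40.0) == [
            (4.0, 5.0, 0.7), (5.0, 40.0, 0.85)]

    def test_segments_clipped_at_horizon(self, default_cfg):
        spec = default_cfg.event("stroke")
        inst = AdverseEventInstance("stroke", 4.0, np.inf, 0.7, 0.85)
        assert event_utility_segments(inst, spec, 4.5) == [(4.0, 4.5, 0.7)]

    def test_onset_beyond_horizon_raises(self, default_cfg):
        spec = default_cfg.event("fracture")
        inst = AdverseEventInstance("fracture", 5.0, 6.0, 0.8)
        with pytest.raises(ValueError):
            event_utility_segments(inst, spec, 4.0)

    def test_osteoporosis_runs_to_end_of_treatment_window(self, cfg):
        for e in cfg.adverse_events:
            e.prob = {k: ((1.0, 1.0) if e.name == "osteoporosis" else (0.0, 0.0))
                      for k in e.prob}
        ev5 = sample_adverse_events(cfg, "five_year", "aromatase_inhibitor", 3)
        ev10 = sample_adverse_events(cfg, "ten_year", "aromatase_inhibitor", 3)
        assert ev5[0].end == 5.0 and ev10[0].end == 10.0
        assert ev5[0].onset == ev10[0].onset   # shared first-5-year onset
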