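"""Adverse-event sampling and utility-decrement segments.

Each grade 3-4 event type (stroke, pulmonary embolus, new cardiac
condition, fracture, endometrial cancer, osteoporosis) is sampled
independently per woman with the cumulative probability of the arm's
column (years 0-5 for the 5-year strategy, 0-10 for the 10-year strategy).
Grade 1-2 symptoms are pooled: one Bernoulli decides whether a woman is
affected, and an affected woman receives exactly
``grade12_events_per_affected`` (default 2) event instances.

Onsets are uniform over the arm's treatment window; an event translates
into one or two (utility multiplier, time span) segments according to its
duration semantics:

* fixed span (fracture 1 y, pulmonary embolus 9 months, grade 1-2 1 y);
* treatment duration (osteoporosis: onset to end of the treatment window);
* lifetime (new cardiac condition);
* first year then lifetime (stroke, endometrial cancer: acute utility for
  one year after onset, then the continuing-care utility for life).

Overlapping decrements combine multiplicatively in the outcomes module.
The source model notes grade 3-4 events could be life-threatening but
publishes no excess-mortality rates, so no adverse-event-attributable
deaths are modelled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import rng
from .params import ScenarioConfig, AdverseEventSpec, EVENT_ORDER, REGIMENS
from .treatment import ARM_DURATION

GRADE34_EVENTS = tuple(e for e in EVENT_ORDER if e != "grade12")


@dataclass
class AdverseEventInstance:
    name: str
    onset: float                 # years post-diagnosis
    end: float                   # years post-diagnosis (inf = lifetime)
    utility_initial: float
    utility_continuing: float | None = None


def _resolve_duration(value, arm_duration: float) -> float:
    return arm_duration if value == "treatment_duration" else float(value)


def effective_probabilities(cfg: ScenarioConfig, arm: str):
    """Per-event, per-regimen probability for one arm, completion-adjusted.

    The 0-5 year portion scales with c1 and the 5-10 year increment with
    c2; with full completion these are just the Table columns.  Returns a
    dict event name -> array over regimen codes.
    """
    c1, c2 = cfg.completion
    out = {}
    for e in cfg.adverse_events:
        probs = np.empty(len(REGIMENS))
        for j, reg in enumerate(REGIMENS):
            p5, p10 = e.prob[reg]
            if arm == "five_year":
                p = c1 * p5
            else:
                p = c1 * p5 + c2 * (p10 - p5)
            probs[j] = min(max(p, 0.0), 1.0)
        out[e.name] = probs
    return out


def sample_event_arrays(cfg: ScenarioConfig, arm: str, regimen_codes: np.ndarray,
                        start: int, stop: int):
    """Occurrence flags and onsets for every event type, CRN-stable.

    One uniform per (woman, event type) decides occurrence in *both* arms:
    the 10-year column probability is cumulative over years 0-10, so a draw
    below the 5-year probability is an event arising while the regimens are
    still identical -- it occurs in both arms at the same onset in (0, 5] --
    while a draw in the increment (p5, p10] is an event of the extension
    years, with onset in (5, 10] in the 10-year arm only.  This keeps the
    first five years of each woman's history identical across arms, and a
    woman's 5-year-arm event set never depends on whether the 10-year arm
    was simulated.
    """
    probs5 = effective_probabilities(cfg, "five_year")
    probs10 = effective_probabilities(cfg, "ten_year")
    p_arm = probs5 if arm == "five_year" else probs10
    occ: dict[str, np.ndarray] = {}
    onset: dict[str, np.ndarray] = {}
    for i, name in enumerate(EVENT_ORDER):
        if name == "grade12":
            u = rng.uniforms(cfg.master_seed, rng.GRADE12_OCC, start, stop)
            occ[name] = u < p_arm[name][regimen_codes]
            onset[name] = np.zeros(stop - start)  # deterministic instances
            continue
        u = rng.uniforms(cfg.master_seed, rng.AE_OCC_BASE + i, start, stop)
        v = rng.uniforms(cfg.master_seed, rng.AE_ONSET_BASE + i, start, stop)
        occ[name] = u < p_arm[name][regimen_codes]
        if arm == "five_year":
            onset[name] = v * 5.0
        else:
            shared = u < np.minimum(probs5[name], probs10[name])[regimen_codes]
            onset[name] = np.where(shared, v * 5.0, 5.0 + v * 5.0)
    return occ, onset


def segment_columns(cfg: ScenarioConfig, arm: str, occ: dict, onset: dict):
    """Flatten sampled events into (start, end, utility) segment columns.

    Absent events collapse to zero-length segments at t=0 so every column
    has the full cohort length (vector-friendly).  ``inf`` ends are clipped
    by the caller at death / horizon.
    """
    dur_arm = ARM_DURATION[arm]
    n = len(next(iter(occ.values())))
    cols = []

    def add(present, s, e, u):
        s = np.where(present, s, 0.0)
        e = np.where(present, np.maximum(e, s), 0.0)
        cols.append((s, e, float(u)))

    for name in GRADE34_EVENTS:
        spec = cfg.event(name)
        p, o = occ[name], onset[name]
        if spec.duration_kind == "fixed":
            d = _resolve_duration(spec.duration, dur_arm)
            add(p, o, o + d, spec.utility)
        elif spec.duration_kind == "treatment_duration":
            add(p, o, np.full(n, dur_arm), spec.utility)
        elif spec.duration_kind == "lifetime":
            add(p, o, np.full(n, np.inf), spec.utility)
        elif spec.duration_kind == "first_year_then_lifetime":
            add(p, o, o + 1.0, spec.utility)
            add(p, o + 1.0, np.full(n, np.inf), spec.utility_continuing)
        else:
            raise ValueError(f"unknown duration kind {spec.duration_kind!r}")

    g12 = cfg.event("grade12")
    k = cfg.grade12_events_per_affected
    d = _resolve_duration(g12.duration, dur_arm)
    p = occ["grade12"]
    for j in range(k):
        u = g12.utility if j == 0 else (g12.utility_second or g12.utility)
        o = np.full(n, j * dur_arm / k)     # first at window start, then evenly spaced
        add(p, o, o + d, u)
    return cols


# ---------------------------------------------------------------------------
# scalar / per-woman API
# ---------------------------------------------------------------------------

def sample_adverse_events(cfg: ScenarioConfig, arm: str, regimen: str,
                          woman_id: int = 0) -> list[AdverseEventInstance]:
    """Event instances for one woman (reads the same CRN streams as the
    vectorized path, so results match the full simulation row-for-row)."""
    code = REGIMENS.index(regimen)
    codes = np.array([code], dtype=np.int8)
    occ, onset = sample_event_arrays(cfg, arm, codes, woman_id, woman_id + 1)
    out = []
    dur_arm = ARM_DURATION[arm]
    for name in GRADE34_EVENTS:
        if not occ[name][0]:
            continue
        spec = cfg.event(name)
        o = float(onset[name][0])
        if spec.duration_kind == "fixed":
            end = o + _resolve_duration(spec.duration, dur_arm)
        elif spec.duration_kind == "treatment_duration":
            end = max(o, dur_arm)
        else:
            end = math.inf
        out.append(AdverseEventInstance(name, o, end, spec.utility,
                                        spec.utility_continuing))
    if occ["grade12"][0]:
        g12 = cfg.event("grade12")
        k = cfg.grade12_events_per_affected
        d = _resolve_duration(g12.duration, dur_arm)
        for j in range(k):
            u = g12.utility if j == 0 else (g12.utility_second or g12.utility)
            o = j * dur_arm / k
            out.append(AdverseEventInstance("grade12", o, o + d, u))
    return out


def event_utility_segments(instance: AdverseEventInstance, spec: AdverseEventSpec,
                           horizon_end: float) -> list[tuple[float, float, float]]:
    """(start, end, utility multiplier) spans for one event, clipped to the
    horizon; two spans for acute-then-continuing events."""
    if instance.onset > horizon_end:
        raise ValueError("onset beyond horizon")
    segs = []
    if spec.duration_kind == "first_year_then_lifetime":
        mid = instance.onset + 1.0
        segs.append((instance.onset, min(mid, horizon_end), spec.utility))
        if mid < horizon_end:
            segs.append((mid, horizon_end, spec.utility_continuing))
    else:
        end = min(instance.end, horizon_end)
        segs.append((instance.onset, end, instance.utility_initial))
    return [(s, e, u) for s, e, u in segs if e > s]
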