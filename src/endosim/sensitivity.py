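"""One-way, two-way, and completion-rate sensitivity analyses.

Every scenario re-runs the full paired simulation under *identical* seeds,
so the only thing that varies between sweep points is the swept parameter
(the base-case point of any sweep is bit-identical to the unperturbed run).
Swept quantities are the adverse-event utilities, probabilities, and
durations over their published ranges; therapy-completion schedules; and
the combined best/worst cases (shortest durations + highest utilities vs
longest durations + lowest utilities).  The headline quantity is the
incremental discounted QALY (10-year minus 5-year arm); a tornado table
orders scenarios by the magnitude of their deviation from the base case.

Probabilistic sensitivity analysis is deliberately out of scope.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ScenarioConfig, ConfigError, REGIMENS
from .natural_history import CalibratedModel, calibrate_scenario
from .outcomes import run_simulation


@dataclass
class SweepSpec:
    path: str                    # e.g. "adverse_events.grade12.duration"
    low: float | str
    high: float | str
    n_points: int = 3
    label: str | None = None

    def points(self, base):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if isinstance(self.low, str) or isinstance(self.high, str) or self.n_points == 3:
            return [self.low, base, self.high]
        return list(np.linspace(self.low, self.high, self.n_points))


@dataclass
class SensitivityResult:
    label: str
    points: list
    increments: list[float]
    base_increment: float

    @property
    def sign_flip(self) -> bool:
        return any(np.sign(i) != np.sign(self.base_increment)
                   for i in self.increments if i != 0)


def set_parameter(cfg: ScenarioConfig, path: str, value) -> None:
    """Set a swept parameter in place.

    Supported paths: ``adverse_events.<event>.utility`` (also
    ``utility_continuing``, ``utility_second``, ``duration``),
    ``adverse_events.<event>.prob_total.<regimen>`` (rescales that event's
    5- and 10-year probabilities proportionally so their total moves to the
    given value), ``grade34_total.<regimen>.<duration>`` (rescales every
    grade 3-4 event proportionally), and plain dotted config keys
    (``discount_rate``, ``completion`` ...).
    """
    parts = path.split(".")
    if parts[0] == "adverse_events" and len(parts) >= 3:
        ev = cfg.event(parts[1])
        attr = parts[2]
        if attr in ("utility", "utility_continuing", "utility_second", "duration"):
            setattr(ev, attr, value)
            return
        if attr == "prob_total" and len(parts) == 4:
            reg = parts[3]
            p5, p10 = ev.prob[reg]
            scale = float(value) / (p5 + p10)
            ev.prob[reg] = (p5 * scale, p10 * scale)
            return
        raise ConfigError(f"unknown sweep path '{path}'")
    if parts[0] == "grade34_total" and len(parts) == 3:
        reg, dur = parts[1], int(parts[2])
        base = cfg.grade34_total(reg, dur)
        scale = float(value) / base
        i = 0 if dur == 5 else 1
        for e in cfg.adverse_events:
            if e.grade_class == "grade34":
                p = list(e.prob[reg])
                p[i] = min(p[i] * scale, 1.0)
                e.prob[reg] = tuple(p)
        return
    from .params import _apply_override
    _apply_override(cfg, path, value)


def _increment(cfg: ScenarioConfig, model: CalibratedModel,
               stratum: str = "all") -> float:
    res = run_simulation(cfg, model)
    return res.diff(stratum, "all", "qaly_disc")


def one_way_sweep(cfg: ScenarioConfig, spec: SweepSpec,
                  model: CalibratedModel | None = None,
                  stratum: str = "all") -> SensitivityResult:
    """Re-simulate at each sweep point under identical seeds."""
    if model is None:
        model = calibrate_scenario(cfg)
    base_cfg = copy.deepcopy(cfg)
    # base value for labelling / midpoint
    base_inc = _increment(base_cfg, model, stratum)
    pts, incs = [], []
    probe = copy.deepcopy(cfg)
    base_val = _read_base(probe, spec.path)
    for p in spec.points(base_val):
        c = copy.deepcopy(cfg)
        set_parameter(c, spec.path, p)
        pts.append(p)
        incs.append(base_inc if _same(p, base_val) else _increment(c, model, stratum))
    return SensitivityResult(spec.label or spec.path, pts, incs, base_inc)


def _same(a, b):
    try:
        return float(a) == float(b)
    except (TypeError, ValueError):
        return a == b


def _read_base(cfg: ScenarioConfig, path: str):
    parts = path.split(".")
    if parts[0] == "adverse_events" and len(parts) >= 3:
        ev = cfg.event(parts[1])
        if parts[2] == "prob_total":
            return sum(ev.prob[parts[3]])
        return getattr(ev, parts[2])
    if parts[0] == "grade34_total":
        return cfg.grade34_total(parts[1], int(parts[2]))
    node = __import__("endosim.params", fromlist=["config_to_dict"]).config_to_dict(cfg)
    for p in parts:
        node = node[int(p)] if isinstance(node, list) else node[p]
    return node


def _extreme_case(cfg: ScenarioConfig, worst: bool) -> ScenarioConfig:
    c = copy.deepcopy(cfg)
    for e in c.adverse_events:
        if e.utility_range:
            e.utility = e.utility_range[0] if worst else e.utility_range[1]
        if e.continuing_range:
            e.utility_continuing = e.continuing_range[0] if worst else e.continuing_range[1]
        if e.utility_second_range:
            e.utility_second = e.utility_second_range[0] if worst else e.utility_second_range[1]
        if e.duration_range:
            e.duration = e.duration_range[1] if worst else e.duration_range[0]
    return c


def two_way_best_worst(cfg: ScenarioConfig, model: CalibratedModel | None = None,
                       stratum: str = "all") -> tuple[SensitivityResult, SensitivityResult]:
    """Worst case (longest durations, lowest utilities) and best case
    (shortest durations, highest utilities); worst <= base <= best."""
    if model is None:
        model = calibrate_scenario(cfg)
    base_inc = _increment(cfg, model, stratum)
    worst = _increment(_extreme_case(cfg, True), model, stratum)
    best = _increment(_extreme_case(cfg, False), model, stratum)
    return (SensitivityResult("worst case (long AEs, low utilities)", ["worst"], [worst], base_inc),
            SensitivityResult("best case (short AEs, high utilities)", ["best"], [best], base_inc))


def completion_scenarios(cfg: ScenarioConfig, schedules,
                         model: CalibratedModel | None = None,
                         stratum: str = "all") -> list[SensitivityResult]:
    """One scenario per (c1, c2) completion schedule."""
    if model is None:
        model = calibrate_scenario(cfg)
    base_inc = _increment(cfg, model, stratum)
    out = []
    for c1, c2 in schedules:
        c = copy.deepcopy(cfg)
        c.completion = (float(c1), float(c2))
        inc = base_inc if (c1, c2) == (1.0, 1.0) else _increment(c, model, stratum)
        out.append(SensitivityResult(f"completion {c1:g}/{c2:g}", [(c1, c2)], [inc], base_inc))
    return out


def tornado_table(results: list[SensitivityResult]) -> pd.DataFrame:
    """Scenarios ordered by |deviation from base| (descending; ties broken
    alphabetically by label)."""
    rows = []
    for r in results:
        if not r.increments:
            continue
        dev = max(abs(i - r.base_increment) for i in r.increments)
        rows.append({"label": r.label,
                     "low_increment": min(r.increments),
                     "high_increment": max(r.increments),
                     "base_increment": r.base_increment,
                     "max_deviation": dev})
    if not rows:
        return pd.DataFrame(columns=["label", "low_increment", "high_increment",
                                     "base_increment", "max_deviation"])
    df = pd.DataFrame(rows)
    return (df.sort_values(["max_deviation", "label"], ascending=[False, True])
              .reset_index(drop=True))


def default_sweeps(cfg: ScenarioConfig) -> list[SweepSpec]:
    """The standard one-way sweep set: utility, probability, and duration
    of each adverse event over its published range."""
    sweeps = []
    for e in cfg.adverse_events:
        if e.utility_range:
            sweeps.append(SweepSpec(f"adverse_events.{e.name}.utility",
                                    *e.utility_range, label=f"{e.name} utility"))
        if e.duration_range:
            sweeps.append(SweepSpec(f"adverse_events.{e.name}.duration",
                                    e.duration_range[0], e.duration_range[1],
                                    label=f"{e.name} duration"))
    for reg in REGIMENS:
        lo5 = sum(e.prob_range[reg][0][0] for e in cfg.adverse_events
                  if e.grade_class == "grade34")
        hi5 = sum(e.prob_range[reg][0][1] for e in cfg.adverse_events
                  if e.grade_class == "grade34")
        base5 = cfg.grade34_total(reg, 5)
        sweeps.append(SweepSpec(f"grade34_total.{reg}.5", lo5, hi5,
                                label=f"grade 3-4 total, {reg}, 5 y"))
    return sweeps
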