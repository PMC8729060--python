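"""Model input parameters: treatment efficacy, adverse events, utilities.

Everything the simulator consumes at run time lives in a ``ScenarioConfig``:
hazard ratios for each strategy (5 vs 10 years of endocrine therapy) by age
band and stage group, adverse-event probabilities / utilities / durations by
regimen and treatment duration, age-band and stage utility weights, the
discount rate, the cohort specification, and calibration targets.  The
bundled defaults carry the published trial-derived inputs verbatim,
including the parenthetical sensitivity ranges.

Also here: the exponential-survival arithmetic that converts trial death
counts into per-arm hazards and a hazard ratio (the route by which the
10-year aromatase-inhibitor HR was derived from the NSABP B-42 counts).
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

REGIMENS = ("tamoxifen", "tamoxifen_os", "aromatase_inhibitor")

#: Event sampling order; also fixes the RNG purpose offsets per event.
EVENT_ORDER = (
    "stroke",
    "pulmonary_embolus",
    "new_cardiac",
    "fracture",
    "endometrial_cancer",
    "osteoporosis",
    "grade12",
)

DURATION_KINDS = ("fixed", "treatment_duration", "lifetime", "first_year_then_lifetime")


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration files."""


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------

@dataclass
class HazardRatioPair:
    """Strategy-level hazard ratios (5- and 10-year vs no endocrine therapy)
    for one age-band x stage-group stratum."""

    age_lo: float
    age_hi: float
    stage_group: str           # "stage1" | "stages23" | "all"
    hr5: float
    hr10: float
    hr5_range: tuple[float, float] | None = None
    hr10_range: tuple[float, float] | None = None


@dataclass
class AdverseEventSpec:
    """One adverse-event type with its per-regimen cumulative probabilities.

    ``prob[regimen] = (p5, p10)`` are cumulative probabilities over years
    0-5 and 0-10 respectively (the 10-year column is cumulative, not
    additive).  ``duration_kind`` selects the decrement semantics; for
    ``fixed`` the span is ``duration`` years.  Ranges are the published
    sensitivity bounds; a duration upper bound of ``"treatment_duration"``
    means the arm's full treatment window.
    """

    name: str
    grade_class: str           # "grade12" | "grade34"
    utility: float
    duration_kind: str
    prob: dict[str, tuple[float, float]]
    prob_range: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=dict)
    utility_range: tuple[float, float] | None = None
    utility_continuing: float | None = None
    continuing_range: tuple[float, float] | None = None
    duration: float | None = None
    duration_range: tuple[float, Any] | None = None  # upper may be "treatment_duration"
    # second-instance utility for pooled grade 1-2 events
    utility_second: float | None = None
    utility_second_range: tuple[float, float] | None = None


@dataclass
class UtilityTable:
    """General-health utility by decade age band and utility by stage at
    diagnosis; combined multiplicatively with toxicity decrements."""

    age_band: dict[int, float]
    stage: dict[str, float]

    def age_utility(self, age: float) -> float:
        band = min(80, max(20, int(age // 10) * 10))
        return self.age_band[band]


@dataclass
class CohortSpec:
    age_range: tuple[float, float] = (25.0, 79.0)
    age_mean: float = 61.0
    age_sd: float = 13.0
    birth_cohort_range: tuple[int, int] = (1935, 2009)
    stage_probs: dict[str, float] = field(default_factory=lambda: {
        "1": 0.45, "2a": 0.25, "2b": 0.18, "3": 0.12})


@dataclass
class CalibrationSpec:
    """Calibration targets: crude lifetime P(BC death) in the 5-year arm and
    the share of the 10-vs-5 mortality difference accrued by year 15, per
    age-band stratum."""

    targets: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "25-49": {"p5": 0.1191, "share15": 2.13 / 2.63},
        "50-79": {"p5": 0.1020, "share15": 0.10 / 0.16},
    })
    node_pos_multiplier: float = 2.5
    weibull_k: float = 1.0
    n_cal: int = 400_000


@dataclass
class ScenarioConfig:
    n_women: int = 100_000
    master_seed: int = 12345
    discount_rate: float = 0.03
    discounting: str = "continuous"          # "continuous" | "annual"
    horizon: str = "lifetime"                # "lifetime" | "15y"
    completion: tuple[float, float] = (1.0, 1.0)   # years 0-5, years 5-10
    max_bc_death_year: float = 25.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    life_table: dict[str, float] = field(default_factory=lambda: {
        "alpha": 5e-4, "beta": 3e-5, "gamma": 0.095})
    life_table_csv: str | None = None
    utilities: UtilityTable = None  # filled by default_scenario
    hazard_ratios: list[HazardRatioPair] = None
    adverse_events: list[AdverseEventSpec] = None
    grade12_events_per_affected: int = 2
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)

    # -- convenience views -------------------------------------------------
    def event(self, name: str) -> AdverseEventSpec:
        for e in self.adverse_events:
            if e.name == name:
                return e
        raise KeyError(name)

    def hr_for(self, age: float, stage: str) -> HazardRatioPair:
        group = "stage1" if stage == "1" else "stages23"
        for h in self.hazard_ratios:
            if h.age_lo <= age <= h.age_hi and h.stage_group in (group, "all"):
                return h
        raise ValueError(f"no hazard-ratio stratum covers age {age}, stage {stage}")

    def grade34_total(self, regimen: str, duration: int) -> float:
        i = 0 if duration == 5 else 1
        return sum(e.prob[regimen][i] for e in self.adverse_events
                   if e.grade_class == "grade34")


# ---------------------------------------------------------------------------
# bundled defaults (published model inputs)
# ---------------------------------------------------------------------------

def _default_events() -> list[AdverseEventSpec]:
    pct = lambda *v: tuple(x / 100.0 for x in v)
    return [
        AdverseEventSpec(
            name="stroke", grade_class="grade34", utility=0.70,
            utility_range=(0.6, 0.8), utility_continuing=0.85,
            continuing_range=(0.75, 0.95), duration_kind="first_year_then_lifetime",
            prob={"tamoxifen": pct(1.85, 2.01), "tamoxifen_os": pct(1.85, 2.01),
                  "aromatase_inhibitor": pct(1.85, 2.01)},
            prob_range={"tamoxifen": (pct(1.75, 2.17), pct(1.67, 2.48)),
                        "tamoxifen_os": (pct(1.68, 2.02), pct(1.84, 2.21)),
                        "aromatase_inhibitor": (pct(1.69, 1.98), pct(1.85, 2.13))}),
        AdverseEventSpec(
            name="pulmonary_embolus", grade_class="grade34", utility=0.65,
            utility_range=(0.6, 0.7), duration_kind="fixed", duration=0.75,
            duration_range=(0.5, 1.0),
            prob={"tamoxifen": pct(3.03, 5.87), "tamoxifen_os": pct(2.30, 4.46),
                  "aromatase_inhibitor": pct(0.83, 0.80)},
            prob_range={"tamoxifen": (pct(2.86, 3.56), pct(4.89, 7.26)),
                        "tamoxifen_os": (pct(2.09, 2.51), pct(4.08, 4.90)),
                        "aromatase_inhibitor": (pct(0.76, 0.89), pct(0.74, 0.85))}),
        AdverseEventSpec(
            name="new_cardiac", grade_class="grade34", utility=0.80,
            utility_range=(0.7, 0.9), duration_kind="lifetime",
            prob={"tamoxifen": pct(2.53, 1.97), "tamoxifen_os": pct(2.53, 1.97),
                  "aromatase_inhibitor": pct(5.06, 5.06)},
            prob_range={"tamoxifen": (pct(2.39, 2.97), pct(1.64, 2.44)),
                        "tamoxifen_os": (pct(2.30, 2.77), pct(1.80, 2.16)),
                        "aromatase_inhibitor": (pct(4.62, 5.41), pct(4.65, 5.37))}),
        AdverseEventSpec(
            name="fracture", grade_class="grade34", utility=0.80,
            utility_range=(0.7, 0.9), duration_kind="fixed", duration=1.0,
            prob={"tamoxifen": pct(1.09, 0.96), "tamoxifen_os": pct(1.74, 1.74),
                  "aromatase_inhibitor": pct(2.80, 5.00)},
            prob_range={"tamoxifen": (pct(1.03, 1.28), pct(0.80, 1.19)),
                        "tamoxifen_os": (pct(1.59, 1.90), pct(1.59, 1.91)),
                        "aromatase_inhibitor": (pct(2.56, 2.99), pct(4.59, 5.31))}),
        AdverseEventSpec(
            name="endometrial_cancer", grade_class="grade34", utility=0.85,
            utility_range=(0.75, 0.95), utility_continuing=0.90,
            continuing_range=(0.85, 0.95), duration_kind="first_year_then_lifetime",
            prob={"tamoxifen": pct(0.98, 1.80), "tamoxifen_os": pct(0.98, 1.80),
                  "aromatase_inhibitor": pct(0.32, 0.59)},
            prob_range={"tamoxifen": (pct(0.93, 1.15), pct(1.50, 2.23)),
                        "tamoxifen_os": (pct(0.89, 1.07), pct(1.65, 1.98)),
                        "aromatase_inhibitor": (pct(0.30, 0.35), pct(0.55, 0.63))}),
        AdverseEventSpec(
            name="osteoporosis", grade_class="grade34", utility=0.90,
            utility_range=(0.85, 0.95), duration_kind="treatment_duration",
            prob={"tamoxifen": pct(13.70, 12.07), "tamoxifen_os": pct(21.90, 22.90),
                  "aromatase_inhibitor": pct(13.71, 14.48)},
            prob_range={"tamoxifen": (pct(12.96, 16.10), pct(10.04, 14.92)),
                        "tamoxifen_os": (pct(19.93, 23.93), pct(20.94, 25.15)),
                        "aromatase_inhibitor": (pct(12.52, 14.66), pct(13.31, 15.37))}),
        AdverseEventSpec(
            name="grade12", grade_class="grade12", utility=0.90,
            utility_range=(0.85, 0.95), utility_second=0.85,
            utility_second_range=(0.75, 0.95),
            duration_kind="fixed", duration=1.0,
            duration_range=(0.5, "treatment_duration"),
            prob={"tamoxifen": pct(71.67, 86.43), "tamoxifen_os": pct(67.06, 80.88),
                  "aromatase_inhibitor": pct(53.40, 64.40)},
            prob_range={"tamoxifen": (pct(68.89, 74.45), pct(82.52, 92.90)),
                        "tamoxifen_os": (pct(64.16, 69.97), pct(77.47, 84.49)),
                        "aromatase_inhibitor": (pct(51.64, 55.15), pct(61.30, 67.51))}),
    ]


def default_scenario() -> ScenarioConfig:
    """The base-case configuration: every published input at its point value,
    100% therapy completion, 3% continuous discounting, lifetime horizon."""
    cfg = ScenarioConfig()
    cfg.utilities = UtilityTable(
        age_band={20: 0.913, 30: 0.893, 40: 0.863, 50: 0.837,
                  60: 0.811, 70: 0.771, 80: 0.724},
        stage={"1": 0.9, "2a": 0.85, "2b": 0.85, "3": 0.8, "4": 0.4},
    )
    cfg.hazard_ratios = [
        HazardRatioPair(25, 49, "stage1", 0.70, 0.54, (0.66, 0.88), (0.51, 0.68)),
        HazardRatioPair(25, 49, "stages23", 0.66, 0.50, (0.62, 0.84), (0.47, 0.64)),
        HazardRatioPair(50, 79, "all", 0.55, 0.54, (0.46, 0.72), None),
    ]
    cfg.adverse_events = _default_events()
    return cfg


# ---------------------------------------------------------------------------
# serialization (canonical YAML round trip)
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if isinstance(obj, (HazardRatioPair, AdverseEventSpec, UtilityTable,
                        CohortSpec, CalibrationSpec, ScenarioConfig)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg: ScenarioConfig) -> dict:
    return _to_plain(cfg)


def _pair(v):
    return None if v is None else tuple(v)


def config_from_dict(d: dict) -> ScenarioConfig:
    base = config_to_dict(default_scenario())
    merged = _merge(base, d, path="")
    cfg = default_scenario()
    cfg.n_women = int(merged["n_women"])
    cfg.master_seed = int(merged["master_seed"])
    cfg.discount_rate = float(merged["discount_rate"])
    cfg.discounting = merged["discounting"]
    cfg.horizon = merged["horizon"]
    cfg.completion = tuple(float(c) for c in merged["completion"])
    cfg.max_bc_death_year = float(merged["max_bc_death_year"])
    co = merged["cohort"]
    cfg.cohort = CohortSpec(
        age_range=tuple(co["age_range"]), age_mean=float(co["age_mean"]),
        age_sd=float(co["age_sd"]),
        birth_cohort_range=tuple(int(x) for x in co["birth_cohort_range"]),
        stage_probs={k: float(v) for k, v in co["stage_probs"].items()})
    cfg.life_table = {k: float(v) for k, v in merged["life_table"].items()}
    cfg.life_table_csv = merged["life_table_csv"]
    u = merged["utilities"]
    cfg.utilities = UtilityTable(age_band={int(k): float(v) for k, v in u["age_band"].items()},
                                 stage={str(k): float(v) for k, v in u["stage"].items()})
    cfg.hazard_ratios = [
        HazardRatioPair(h["age_lo"], h["age_hi"], h["stage_group"], h["hr5"], h["hr10"],
                        _pair(h["hr5_range"]), _pair(h["hr10_range"]))
        for h in merged["hazard_ratios"]]
    cfg.adverse_events = []
    for e in merged["adverse_events"]:
        dr = e["duration_range"]
        if dr is not None:
            dr = (float(dr[0]), dr[1] if dr[1] == "treatment_duration" else float(dr[1]))
        cfg.adverse_events.append(AdverseEventSpec(
            name=e["name"], grade_class=e["grade_class"], utility=float(e["utility"]),
            duration_kind=e["duration_kind"],
            prob={k: tuple(float(x) for x in v) for k, v in e["prob"].items()},
            prob_range={k: tuple(tuple(float(x) for x in p) for p in v)
                        for k, v in e["prob_range"].items()},
            utility_range=_pair(e["utility_range"]),
            utility_continuing=e["utility_continuing"],
            continuing_range=_pair(e["continuing_range"]),
            duration=e["duration"], duration_range=dr,
            utility_second=e["utility_second"],
            utility_second_range=_pair(e["utility_second_range"])))
    cfg.grade12_events_per_affected = int(merged["grade12_events_per_affected"])
    ca = merged["calibration"]
    cfg.calibration = CalibrationSpec(
        targets={k: {kk: float(vv) for kk, vv in v.items()} for k, v in ca["targets"].items()},
        node_pos_multiplier=float(ca["node_pos_multiplier"]),
        weibull_k=float(ca["weibull_k"]), n_cal=int(ca["n_cal"]))
    return cfg


#: Mapping-valued leaves that users may replace wholesale (arbitrary keys).
_LEAF_MAPS = {"utilities.age_band", "utilities.stage", "cohort.stage_probs",
              "life_table", "calibration.targets"}


def _merge(base, update, path):
    """Deep-merge ``update`` into ``base``; unknown keys are configuration errors."""
    if isinstance(base, dict):
        if not isinstance(update, dict):
            raise ConfigError(f"expected mapping at '{path or '<root>'}'")
        out = dict(base)
        for k, v in update.items():
            child = path + str(k)
            if str(k) not in {str(b) for b in base}:
                raise ConfigError(f"unknown configuration key '{child}'")
            if isinstance(base[k], dict) and child not in _LEAF_MAPS:
                out[k] = _merge(base[k], v, child + ".")
            else:
                out[k] = v
        return out
    return update


def save_scenario_config(cfg: ScenarioConfig, path=None) -> str:
    """Canonical serialization (sorted keys, block style): save->load->save
    is byte-stable."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=True,
                          default_flow_style=False, allow_unicode=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_scenario_config(path=None, overrides: dict | None = None) -> ScenarioConfig:
    """Load a config file on top of the bundled defaults.

    ``path=None`` or an empty file yields the defaults.  ``overrides`` maps
    dotted key paths (e.g. ``discount_rate`` or ``cohort.age_mean``) to
    values; unknown paths raise :class:`ConfigError`.
    """
    d: dict = {}
    if path is not None:
        with open(path) as fh:
            try:
                d = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"configuration file {path} must contain a mapping")
    cfg = config_from_dict(d)
    for key, value in (overrides or {}).items():
        _apply_override(cfg, key, value)
    return cfg


def _apply_override(cfg: ScenarioConfig, dotted: str, value) -> None:
    d = config_to_dict(cfg)
    node = d
    parts = dotted.split(".")
    for p in parts[:-1]:
        if isinstance(node, list):
            node = node[int(p)]
        elif isinstance(node, dict) and p in node:
            node = node[p]
        else:
            raise ConfigError(f"unknown configuration key '{dotted}'")
    leaf = parts[-1]
    if isinstance(node, list):
        node[int(leaf)] = value
    elif isinstance(node, dict) and leaf in node:
        node[leaf] = value
    else:
        raise ConfigError(f"unknown configuration key '{dotted}'")
    new = config_from_dict(d)
    cfg.__dict__.update(new.__dict__)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    field: str
    value: Any
    rule: str

    def __str__(self):
        return f"{self.field}={self.value!r}: {self.rule}"


def validate_parameters(cfg: ScenarioConfig) -> list[Violation]:
    """Check every structural invariant; returns a (possibly empty) report.

    Validation never raises: each breach becomes one entry naming the field,
    the offending value, and the violated rule.
    """
    v: list[Violation] = []

    def check(ok, fieldname, value, rule):
        if not ok:
            v.append(Violation(fieldname, value, rule))

    check(cfg.discount_rate >= 0, "discount_rate", cfg.discount_rate, "must be >= 0")
    check(cfg.n_women >= 0, "n_women", cfg.n_women, "must be >= 0")
    for i, c in enumerate(cfg.completion):
        check(0 < c <= 1, f"completion[{i}]", c, "must lie in (0, 1]")
    check(cfg.horizon in ("lifetime", "15y"), "horizon", cfg.horizon,
          "must be 'lifetime' or '15y'")

    sp = sum(cfg.cohort.stage_probs.values())
    check(abs(sp - 1.0) <= 1e-12, "cohort.stage_probs", sp, "must sum to 1")
    lo, hi = cfg.cohort.age_range
    check(lo < hi, "cohort.age_range", cfg.cohort.age_range, "lo < hi required")

    for h in cfg.hazard_ratios:
        label = f"hazard_ratios[{h.age_lo}-{h.age_hi}/{h.stage_group}]"
        check(0 < h.hr5 <= 1, label + ".hr5", h.hr5, "must lie in (0, 1]")
        check(0 < h.hr10 <= 1, label + ".hr10", h.hr10, "must lie in (0, 1]")
        if h.age_hi <= 49:  # tamoxifen strata: extension strictly helps
            check(h.hr10 <= h.hr5, label, (h.hr5, h.hr10),
                  "hr10 must not exceed hr5 for tamoxifen strata")

    bands = sorted(cfg.utilities.age_band)
    vals = [cfg.utilities.age_band[b] for b in bands]
    for b, x in zip(bands, vals):
        check(0 < x <= 1, f"utilities.age_band[{b}]", x, "must lie in (0, 1]")
    check(all(a >= b for a, b in zip(vals, vals[1:])), "utilities.age_band", vals,
          "must be non-increasing with age band")
    stage_order = ["1", "2a", "2b", "3", "4"]
    svals = [cfg.utilities.stage[s] for s in stage_order if s in cfg.utilities.stage]
    check(all(a >= b for a, b in zip(svals, svals[1:])), "utilities.stage", svals,
          "must be non-increasing from stage 1 to 4")
    for s, x in cfg.utilities.stage.items():
        check(0 < x <= 1, f"utilities.stage[{s}]", x, "must lie in (0, 1]")

    for e in cfg.adverse_events:
        check(e.duration_kind in DURATION_KINDS, f"{e.name}.duration_kind",
              e.duration_kind, f"must be one of {DURATION_KINDS}")
        check(0 < e.utility <= 1, f"{e.name}.utility", e.utility, "must lie in (0, 1]")
        if e.utility_continuing is not None:
            check(0 < e.utility_continuing <= 1, f"{e.name}.utility_continuing",
                  e.utility_continuing, "must lie in (0, 1]")
        if e.duration_kind == "fixed":
            check(e.duration is not None and e.duration > 0, f"{e.name}.duration",
                  e.duration, "fixed duration must be positive")
        for reg, (p5, p10) in e.prob.items():
            check(0 <= p5 <= 1, f"{e.name}.prob[{reg}].prob_5y", p5, "must lie in [0, 1]")
            check(0 <= p10 <= 1, f"{e.name}.prob[{reg}].prob_10y", p10, "must lie in [0, 1]")
    check(cfg.grade12_events_per_affected >= 1, "grade12_events_per_affected",
          cfg.grade12_events_per_affected, "must be >= 1")

    check(cfg.calibration.node_pos_multiplier >= 1, "calibration.node_pos_multiplier",
          cfg.calibration.node_pos_multiplier, "must be >= 1")
    for key, tgt in cfg.calibration.targets.items():
        check(0 < tgt["p5"] < 1, f"calibration.targets[{key}].p5", tgt["p5"],
              "must lie in (0, 1)")
        check(0 < tgt["share15"] < 1, f"calibration.targets[{key}].share15",
              tgt["share15"], "must lie in (0, 1)")
    return v


# ---------------------------------------------------------------------------
# trial-count -> hazard arithmetic
# ---------------------------------------------------------------------------

def trial_counts_to_hazards(deaths_a: int, n_a: int, deaths_b: int, n_b: int,
                            followup_years: float = 7.0) -> tuple[float, float, float]:
    """Per-arm constant hazards and their ratio from trial death counts.

    Assumes exponential survival over the follow-up window, so
    ``hazard = -ln(1 - deaths/n) / followup_years``.  The ratio cancels the
    follow-up time and is therefore invariant to it; ``followup_years`` only
    scales the absolute hazards.
    """
    for deaths, n, arm in ((deaths_a, n_a, "a"), (deaths_b, n_b, "b")):
        if n <= 0:
            raise ValueError(f"arm {arm}: n must be positive")
        if not 0 <= deaths <= n:
            raise ValueError(f"arm {arm}: deaths must lie in [0, n]")
        if deaths == n:
            raise ValueError(f"arm {arm}: all subjects died; hazard is infinite")
    if followup_years <= 0:
        raise ValueError("followup_years must be positive")
    hz_a = -math.log1p(-deaths_a / n_a) / followup_years
    hz_b = -math.log1p(-deaths_b / n_b) / followup_years
    return hz_a, hz_b, hz_a / hz_b


def extend_hr(hr5: float, incremental_ratio: float) -> float:
    """10-year strategy HR as the 5-year HR times the incremental hazard
    ratio of extended vs stopped therapy."""
    return hr5 * incremental_ratio


# ---------------------------------------------------------------------------
# parameter export
# ---------------------------------------------------------------------------

def export_parameters_csv(cfg: ScenarioConfig, path=None) -> str:
    """CSV mirroring the published input-parameter panel: one row per
    adverse event x regimen x duration, plus HR and utility panels."""
    buf = io.StringIO()
    buf.write("panel,item,regimen,duration_years,value,low,high\n")
    for h in cfg.hazard_ratios:
        label = f"ages {h.age_lo:g}-{h.age_hi:g} {h.stage_group}"
        for dur, hr, rng in ((5, h.hr5, h.hr5_range), (10, h.hr10, h.hr10_range)):
            lo, hi = rng if rng else ("", "")
            buf.write(f"hazard_ratio,{label},,{dur},{hr},{lo},{hi}\n")
    for e in cfg.adverse_events:
        for reg in REGIMENS:
            for i, dur in enumerate((5, 10)):
                p = e.prob[reg][i]
                lo, hi = e.prob_range.get(reg, ((None, None), (None, None)))[i]
                buf.write(f"ae_probability,{e.name},{reg},{dur},{p:.6f},{lo},{hi}\n")
        lo, hi = e.utility_range or ("", "")
        buf.write(f"ae_utility,{e.name},,,{e.utility},{lo},{hi}\n")
    for band, u in sorted(cfg.utilities.age_band.items()):
        buf.write(f"age_utility,{band}s,,,{u},,\n")
    for s, u in cfg.utilities.stage.items():
        buf.write(f"stage_utility,stage {s},,,{u},,\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
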