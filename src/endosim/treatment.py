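"""Regimen assignment and treatment-effect machinery.

Regimens follow age and stage: women under 50 receive tamoxifen (with
ovarian suppression if node-positive), women 50+ an aromatase inhibitor;
stage 2-3 disease adds chemotherapy (inert here: its mortality effect is
absorbed into the calibrated baseline, its quality-of-life effect into the
stage utility).

Strategy-level hazard ratios are converted into piecewise hazard
multipliers: both arms share the first-5-year multiplier (therapy is
identical there), and the 10-year arm's tail multiplier on (5, 25] is
solved so its lifetime effect equals the published 10-year HR:

    m_tail = (hr10 * Lambda25 - hr5 * Lambda5) / (Lambda25 - Lambda5).

Therapy-completion scenarios scale efficacy linearly on the (1 - HR) scale
and adverse-event probabilities by the same fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ScenarioConfig, HazardRatioPair
from .natural_history import BaselineParams

ARMS = ("five_year", "ten_year")
ARM_DURATION = {"five_year": 5.0, "ten_year": 10.0}


@dataclass
class RegimenAssignment:
    regimen: str                 # tamoxifen | tamoxifen_os | aromatase_inhibitor
    chemo: bool
    trastuzumab: bool            # carried for reporting fidelity; inert
    hr_pair: HazardRatioPair


@dataclass
class ArmMultipliers:
    arm: str
    m_early: float               # hazard multiplier on (0, 5]
    m_tail: float                # hazard multiplier on (5, 25]


def assign_regimen(age_dx: float, stage: str, cfg: ScenarioConfig) -> RegimenAssignment:
    """Deterministic regimen by age and stage (scalar version)."""
    lo, hi = cfg.cohort.age_range
    if not 25.0 <= age_dx <= 79.0:
        raise ValueError(f"age at diagnosis {age_dx} outside [25, 79]")
    node_pos = stage in ("2b", "3")
    if age_dx < 50:
        regimen = "tamoxifen_os" if node_pos else "tamoxifen"
    else:
        regimen = "aromatase_inhibitor"
    chemo = stage != "1"
    return RegimenAssignment(regimen=regimen, chemo=chemo, trastuzumab=False,
                             hr_pair=cfg.hr_for(age_dx, stage))


def assign_regimen_arrays(age_dx: np.ndarray, stage_idx: np.ndarray,
                          cfg: ScenarioConfig):
    """Vectorized regimen assignment.

    Returns (regimen codes indexing params.REGIMENS, hr5, hr10, chemo flag).
    """
    node_pos = stage_idx >= 2
    young = age_dx < 50
    regimen = np.where(young, np.where(node_pos, 1, 0), 2).astype(np.int8)
    hr5 = np.empty_like(age_dx)
    hr10 = np.empty_like(age_dx)
    stage1 = stage_idx == 0
    for mask, age_probe, st in ((young & stage1, 40.0, "1"),
                                (young & ~stage1, 40.0, "2a"),
                                (~young, 65.0, "1")):
        if mask.any():
            h = cfg.hr_for(age_probe, st)
            hr5[mask] = h.hr5
            hr10[mask] = h.hr10
    chemo = ~stage1
    return regimen, hr5, hr10, chemo


def effective_hrs(hr5, hr10, completion=(1.0, 1.0)):
    """Completion-adjusted strategy HRs.

    Efficacy scales linearly on the hazard-reduction scale: the first
    5 years carry fraction ``c1`` of the 5-year effect, and the incremental
    effect of years 5-10 carries fraction ``c2``:

        hr5_eff  = 1 - c1 * (1 - hr5)
        hr10_eff = hr5_eff - c2 * (hr5 - hr10)

    With c1 = c2 = c this reduces to 1 - c * (1 - hr10).
    """
    c1, c2 = completion
    if not (0 < c1 <= 1 and 0 < c2 <= 1):
        raise ValueError("completion fractions must lie in (0, 1]")
    hr5 = np.asarray(hr5, dtype=float)
    hr10 = np.asarray(hr10, dtype=float)
    hr5_eff = 1.0 - c1 * (1.0 - hr5)
    hr10_eff = hr5_eff - c2 * (hr5 - hr10)
    return hr5_eff, hr10_eff


def tail_multiplier(hr5, hr10, Lambda5, Lambda25):
    """Ten-year-arm tail multiplier on (5, 25] (the 5-year arm's tail is
    simply hr5: the benefit of years 0-5 of therapy persists)."""
    Lambda5 = np.asarray(Lambda5, dtype=float)
    Lambda25 = np.asarray(Lambda25, dtype=float)
    if np.any(Lambda25 <= Lambda5) or np.any(Lambda5 < 0):
        raise ValueError("need Lambda25 > Lambda5 >= 0")
    m = (hr10 * Lambda25 - hr5 * Lambda5) / (Lambda25 - Lambda5)
    if np.any(m <= 0):
        raise ValueError("inputs inconsistent with the piecewise model (m_tail <= 0)")
    return m


def arm_multipliers(hr5_eff, hr10_eff, F5, arm: str):
    """Piecewise multipliers for one arm given the effective HRs and the
    baseline's CDF value at 5 years (Lambda5/Lambda25)."""
    if arm == "five_year":
        return hr5_eff, hr5_eff
    m_tail = tail_multiplier(hr5_eff, hr10_eff, F5, 1.0)
    return hr5_eff, m_tail


def evaluate_bc_death(E, m_early, m_tail, lambda_total, shape):
    """Breast-cancer death time (years post-diagnosis) or inf.

    The effective cumulative hazard is M(t) = m_early*Lambda(t) on (0, 5]
    and M(5) + m_tail*(Lambda(t)-Lambda(5)) beyond; a woman dies of BC
    (absent competing death) iff her latent exponential E < M(25), at
    t = M^{-1}(E).  Monotone coupling: with the same E, smaller multipliers
    never give an earlier death.
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    lam = np.broadcast_to(np.asarray(lambda_total, dtype=float), E.shape)
    m_early = np.broadcast_to(np.asarray(m_early, dtype=float), E.shape)
    m_tail = np.broadcast_to(np.asarray(m_tail, dtype=float), E.shape)
    F5 = float(shape.cdf(5.0))
    M5 = m_early * lam * F5
    M25 = M5 + m_tail * lam * (1.0 - F5)
    t = np.full(E.shape, np.inf)
    early = E < M5
    if np.any(early):
        t[early] = shape.quantile(E[early] / (m_early[early] * lam[early]))
    late = (~early) & (E < M25)
    if np.any(late):
        q = F5 + (E[late] - M5[late]) / (m_tail[late] * lam[late])
        t[late] = shape.quantile(q)
    return t
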