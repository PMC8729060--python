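"""Synthetic diagnosed cohort: U.S. women ages 25-79 with ER+ stage 1-3 cancer.

The published model generates diagnosed women from an incidence and
screening front-end; this package instead samples the post-diagnosis state
directly: a continuous age at diagnosis (truncated normal, configurable), a
stage mix over {1, 2a, 2b, 3}, and the deterministic stage->nodal mapping
(stages 1 and 2a node-negative; 2b and 3 node-positive).  Birth year follows
from the birth-cohort window.  Other-cause death ages come from the life
table by inverse transform, conditional on survival to diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import rng
from .lifetable import LifeTable, MAX_AGE
from .params import CohortSpec

STAGES = ("1", "2a", "2b", "3")
NODE_POSITIVE_STAGES = ("2b", "3")


@dataclass
class WomanProfile:
    """One simulated diagnosed woman (scalar view of the columnar cohort)."""

    id: int
    age_dx: float
    birth_year: int
    stage: str
    nodal: str            # "negative" | "positive"
    age_band: int         # decade band start, for utility lookup
    regimen: str | None = None


class Cohort:
    """Columnar cohort container (numpy arrays, one row per woman)."""

    def __init__(self, ids, age_dx, birth_year, stage_idx):
        self.ids = ids
        self.age_dx = age_dx
        self.birth_year = birth_year
        self.stage_idx = stage_idx          # index into STAGES

    def __len__(self):
        return len(self.ids)

    @property
    def stage(self):
        return np.array(STAGES, dtype=object)[self.stage_idx]

    @property
    def node_positive(self):
        return self.stage_idx >= 2

    def profiles(self) -> list[WomanProfile]:
        """Materialize scalar profiles (intended for small cohorts)."""
        out = []
        for i in range(len(self)):
            st = STAGES[self.stage_idx[i]]
            out.append(WomanProfile(
                id=int(self.ids[i]), age_dx=float(self.age_dx[i]),
                birth_year=int(self.birth_year[i]), stage=st,
                nodal=nodal_status(st),
                age_band=int(self.age_dx[i] // 10) * 10))
        return out


def nodal_status(stage: str) -> str:
    """Deterministic stage -> nodal mapping (1, 2a negative; 2b, 3 positive)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return "positive" if stage in NODE_POSITIVE_STAGES else "negative"


def _truncnorm_ppf(u, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_cohort(spec: CohortSpec, seed: int, start: int = 0,
                  n: int | None = None) -> Cohort:
    """Sample ``n`` women (ids ``start..start+n-1``) from the cohort spec.

    Reproducible: the same (spec, seed) always yields the same cohort, and a
    woman's draws depend only on her id, so sub-ranges of a larger cohort
    are identical to the corresponding slice of the full cohort.
    """
    if n is None:
        raise ValueError("n must be given")
    ids = np.arange(start, start + n, dtype=np.int64)
    if n == 0:
        return Cohort(ids, np.empty(0), np.empty(0, dtype=np.int64),
                      np.empty(0, dtype=np.int64))
    lo, hi = spec.age_range
    u_age = rng.uniforms(seed, rng.AGE_DX, start, start + n)
    age_dx = _truncnorm_ppf(u_age, spec.age_mean, spec.age_sd, lo, hi)
    np.clip(age_dx, lo, hi, out=age_dx)

    probs = np.array([spec.stage_probs.get(s, 0.0) for s in STAGES])
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    u_stage = rng.uniforms(seed, rng.STAGE, start, start + n)
    stage_idx = np.searchsorted(cum, u_stage, side="left").astype(np.int64)

    # birth year: uniform over the cohort window, deterministic in id via the
    # stage stream's complement to avoid an extra purpose (kept simple: reuse
    # the fractional part of the age draw -- birth year is inert downstream).
    by_lo, by_hi = spec.birth_cohort_range
    birth_year = (by_lo + ((u_age * 1e6) % 1.0) * (by_hi - by_lo + 1)).astype(np.int64)
    np.clip(birth_year, by_lo, by_hi, out=birth_year)
    return Cohort(ids, age_dx, birth_year, stage_idx)


def sample_other_cause_death_age(age_dx, table: LifeTable, u, birth_year=None):
    """Other-cause death age by inverse transform of the conditional
    survival S(a | a > age_dx); strictly increasing in ``u``."""
    return table.sample_death_age(age_dx, u, birth_year=birth_year)


def cohort_other_cause_death_ages(cohort: Cohort, table: LifeTable, seed: int):
    start, stop = int(cohort.ids[0]) if len(cohort) else 0, (int(cohort.ids[-1]) + 1) if len(cohort) else 0
    u = rng.uniforms(seed, rng.OTHER_CAUSE, start, stop)
    ages = sample_other_cause_death_age(cohort.age_dx, table, u,
                                        birth_year=cohort.birth_year)
    return np.minimum(ages, MAX_AGE)
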