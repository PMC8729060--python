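"""Other-cause (competing) mortality via a Gompertz–Makeham life table.

The simulator needs, for each diagnosed woman, an age at death from causes
other than breast cancer, conditional on being alive at diagnosis.  The
default is a parametric Gompertz–Makeham hazard

    mu(a) = alpha + beta * exp(gamma * a)

with closed-form cumulative hazard H(a) = alpha*a + (beta/gamma)(e^{gamma a} - 1).
Default parameters are a synthetic approximation to U.S. female cohort
mortality (remaining life expectancy ~40 y at age 40, ~14 y at age 70); the
cohort life tables the published model draws on are not public, so absolute
life-year levels are approximate by construction.  A tabulated (age, annual
hazard) override is supported for users with their own life table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_AGE = 120.0

DEFAULT_ALPHA = 5e-4
DEFAULT_BETA = 3e-5
DEFAULT_GAMMA = 0.095

_GRID_STEP = 0.05


@dataclass
class LifeTable:
    """Closed-form Makeham life table with optional tabulated override.

    ``cohort_shift`` maps birth-decade start year -> multiplicative hazard
    factor (secular trend hook); default empty = flat across cohorts.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    tabulated: np.ndarray | None = None  # shape (k, 2): integer age, annual hazard
    cohort_shift: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        ages = np.arange(0.0, MAX_AGE + _GRID_STEP, _GRID_STEP)
        if self.tabulated is not None:
            tab = np.asarray(self.tabulated, dtype=float)
            haz = np.interp(ages, tab[:, 0], tab[:, 1])
            H = np.concatenate([[0.0], np.cumsum(0.5 * (haz[1:] + haz[:-1]) * _GRID_STEP)])
        else:
            H = self.alpha * ages + (self.beta / self.gamma) * np.expm1(self.gamma * ages)
        self._ages = ages
        self._H = H

    # -- hazard / survival -------------------------------------------------
    def hazard(self, age):
        age = np.asarray(age, dtype=float)
        if self.tabulated is not None:
            tab = np.asarray(self.tabulated, dtype=float)
            return np.interp(age, tab[:, 0], tab[:, 1])
        return self.alpha + self.beta * np.exp(self.gamma * age)

    def cumulative_hazard(self, age):
        age = np.asarray(age, dtype=float)
        if self.tabulated is None:
            return self.alpha * age + (self.beta / self.gamma) * np.expm1(self.gamma * age)
        return np.interp(age, self._ages, self._H)

    def survival(self, age):
        return np.exp(-self.cumulative_hazard(age))

    def shift_factor(self, birth_year):
        """Multiplicative hazard factor by birth decade (1.0 if unset)."""
        if not self.cohort_shift:
            return np.ones_like(np.asarray(birth_year, dtype=float))
        decades = (np.asarray(birth_year, dtype=int) // 10) * 10
        return np.array([self.cohort_shift.get(int(d), 1.0) for d in np.ravel(decades)]).reshape(np.shape(decades))

    # -- sampling ----------------------------------------------------------
    def sample_death_age(self, age_now, u, birth_year=None):
        """Inverse-transform a death age conditional on survival to ``age_now``.

        Solves H(a) = H(age_now) - ln(1-u) / shift on the precomputed grid
        (monotone interpolation).  Returns ages capped at ``MAX_AGE``.
        """
        age_now = np.asarray(age_now, dtype=float)
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("u must lie strictly inside (0, 1)")
        shift = 1.0 if birth_year is None else self.shift_factor(birth_year)
        target = self.cumulative_hazard(age_now) - np.log1p(-u) / shift
        age = np.interp(target, self._H, self._ages, right=MAX_AGE)
        return np.maximum(age, age_now + 1e-9)

    def remaining_life_expectancy(self, age: float) -> float:
        """Numerical integral of conditional survival from ``age`` to MAX_AGE."""
        grid = np.arange(age, MAX_AGE + _GRID_STEP, _GRID_STEP)
        s = np.exp(-(self.cumulative_hazard(grid) - self.cumulative_hazard(age)))
        return float(np.trapezoid(s, grid))


def build_life_table(alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                     gamma: float = DEFAULT_GAMMA,
                     cohort_shift: dict[int, float] | None = None) -> LifeTable:
    return LifeTable(alpha=alpha, beta=beta, gamma=gamma,
                     cohort_shift=cohort_shift or {})


def load_life_table_csv(path) -> LifeTable:
    """Life table from a 2-column CSV (integer age, annual hazard)."""
    tab = np.loadtxt(path, delimiter=",", dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise ValueError("life-table CSV must have two columns: age, annual hazard")
    return LifeTable(tabulated=tab)
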