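"""Abridged life tables and standardized-mortality-unit risk differences.

Total mortality is the sum of the eight cause-specific rates (causes are
treated as additive and independent); when one cause is placed on a
counterfactual path the other seven stay on the base-case. Age-specific rates
are converted to conditional death probabilities under a
constant-hazard-within-interval convention by default, with the classic
midpoint (a_x = n/2) actuarial conversion available as an alternative. One SMU
(standardized mortality unit) is a change of 1e-4 in the conditional risk of
death within an age group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import AGE_STARTS, CAUSES, N_AGE_GROUPS, SEXES
from .trajectories import SCENARIOS, TrajectorySet

__all__ = [
    "SMU_SIZE",
    "CONVENTIONS",
    "rate_to_conditional_prob",
    "build_life_table",
    "LifeTable",
    "total_mortality",
    "total_mortality_all",
    "delta_smu",
]

#: Risk-of-death change represented by one standardized mortality unit.
SMU_SIZE = 1e-4

RADIX = 100_000.0

AGE_WIDTH = 5.0

CONVENTIONS = ("constant_hazard", "midpoint")


def rate_to_conditional_prob(m, age_index, *, convention: str = "constant_hazard", ax=None):
    """Convert an age-specific mortality rate to the conditional probability of
    dying within the interval, given survival to its start.

    For closed 5-year intervals the default is q = 1 - exp(-n*m) (constant
    hazard within the interval). The ``midpoint`` convention uses
    q = n*m / (1 + (n - a_x)*m) with a_x defaulting to n/2 (mean years lived in
    the interval by those dying in it). The terminal open interval always has
    q = 1: it exhausts survivorship. Broadcasts over arrays; ``age_index`` may
    be scalar or an array of group indices 0..19.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("mortality rate must be finite and >= 0")
    age_index = np.asarray(age_index)
    terminal = age_index == N_AGE_GROUPS - 1
    if convention == "constant_hazard":
        q = 1.0 - np.exp(-AGE_WIDTH * m)
    else:
        a_x = AGE_WIDTH / 2.0 if ax is None else float(ax)
        q = AGE_WIDTH * m / (1.0 + (AGE_WIDTH - a_x) * m)
    q = np.where(terminal, 1.0, np.minimum(q, 1.0))
    return float(q) if q.ndim == 0 else q


@dataclass(frozen=True)
class LifeTable:
    """Abridged period life table columns over the 20-group age grid.

    Arrays may carry leading batch dimensions (e.g. country x sex x year); the
    age axis is always last. ``q`` is the conditional probability of dying in
    the interval, ``l`` survivors at the interval start (radix 100,000), ``L``
    person-years lived in the interval, ``T`` person-years remaining, and ``e``
    the remaining life expectancy at the interval start.
    """

    q: np.ndarray = field(repr=False)
    l: np.ndarray = field(repr=False)
    L: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)
    e: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        if self.q.ndim != 1:
            raise ValueError("to_frame is defined for a single (unbatched) life table")
        return pd.DataFrame(
            {
                "age_start": AGE_STARTS,
                "q_conditional_prob": self.q,
                "l_survivors": self.l,
                "L_person_years": self.L,
                "T_person_years_remaining": self.T,
                "e_life_expectancy_years": self.e,
            }
        )


def build_life_table(m_schedule, *, convention: str = "constant_hazard", ax=None) -> LifeTable:
    """Build an abridged life table from 20 age-specific total mortality rates.

    Person-years in closed intervals follow the exponential-survivorship
    convention matching the default q conversion (L = d/m for m > 0, else n*l);
    under the ``midpoint`` convention L = n*(l - d) + a_x*d. The terminal open
    interval assumes a constant hazard, L = l/m, so its rate must be positive
    whenever anyone survives to it.
    """
    m = np.asarray(m_schedule, dtype=float)
    if m.shape[-1] != N_AGE_GROUPS:
        raise ValueError(f"expected {N_AGE_GROUPS} age-specific rates on the last axis, got {m.shape}")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("mortality rates must be finite and >= 0")

    q = rate_to_conditional_prob(m, np.arange(N_AGE_GROUPS), convention=convention, ax=ax)
    q = np.atleast_1d(np.asarray(q))

    # Survivorship by cumulative product of survival probabilities.
    surv = np.cumprod(1.0 - q[..., :-1], axis=-1)
    l = np.concatenate(
        [np.full(q.shape[:-1] + (1,), RADIX), RADIX * surv], axis=-1
    )
    d = l * q

    if np.any((m[..., -1] == 0) & (l[..., -1] > 0)):
        raise ValueError(
            "terminal age group has zero mortality rate while survivors remain: "
            "person-years would be infinite; floor the rate (e.g. at 1e-10) before building the table"
        )

    L = np.empty_like(l)
    closed_m = m[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        if convention == "constant_hazard":
            L[..., :-1] = np.where(closed_m > 0, d[..., :-1] / np.where(closed_m > 0, closed_m, 1.0),
                                   AGE_WIDTH * l[..., :-1])
        else:
            a_x = AGE_WIDTH / 2.0 if ax is None else float(ax)
            L[..., :-1] = AGE_WIDTH * (l[..., :-1] - d[..., :-1]) + a_x * d[..., :-1]
        term_m = m[..., -1]
        L[..., -1] = np.where(l[..., -1] > 0, l[..., -1] / np.where(term_m > 0, term_m, 1.0), 0.0)

    T = np.cumsum(L[..., ::-1], axis=-1)[..., ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)

    squeeze = np.asarray(m_schedule).ndim == 1
    if squeeze and q.ndim > np.asarray(m_schedule).ndim:
        q, l, L, T, e = (a[0] for a in (q, l, L, T, e))
    return LifeTable(q=q, l=l, L=L, T=T, e=e)


def total_mortality(traj: TrajectorySet, cause_altered: str, scenario: str) -> np.ndarray:
    """Total rate ``[country, sex, year, age]`` with one cause on its scenario
    path and the remaining seven on the base-case."""
    if cause_altered not in CAUSES:
        raise ValueError(f"unknown cause {cause_altered!r}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    d = CAUSES.index(cause_altered)
    k = SCENARIOS.index(scenario)
    base_total = traj.rates[:, :, :, 0].sum(axis=2)  # [c, s, year, age]
    if scenario == "base":  # exact identity regardless of the altered cause
        return base_total
    return base_total - traj.rates[:, :, d, 0] + traj.rates[:, :, d, k]


def total_mortality_all(traj: TrajectorySet) -> np.ndarray:
    """Total rates ``[country, sex, cause_altered, scenario, year, age]`` for
    all 8 x 3 (cause, scenario) substitutions at once."""
    base_total = traj.rates[:, :, :, 0].sum(axis=2)  # [c, s, y, a]
    # total(d, k) = base_total - base(d) + path(d, k)
    out = (
        base_total[:, :, None, None]
        - traj.rates[:, :, :, 0][:, :, :, None]
        + traj.rates
    )
    # base slice is the identity substitution: keep it exact
    out[:, :, :, 0] = base_total[:, :, None]
    return out


def delta_smu(q_base, q_scenario):
    """Risk difference in standardized mortality units: (q_base - q_scenario) / 1e-4.

    Positive when the scenario risk is lower than the base-case.
    """
    q_base = np.asarray(q_base, dtype=float)
    q_scenario = np.asarray(q_scenario, dtype=float)
    for name, q in (("q_base", q_base), ("q_scenario", q_scenario)):
        if np.any((q < 0) | (q > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = (q_base - q_scenario) / SMU_SIZE
    return float(out) if out.ndim == 0 else out
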