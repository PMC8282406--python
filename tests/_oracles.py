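"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation: fine-step cohort simulation instead of life-table columns,
explicit sort-and-interpolate quantiles instead of np.quantile inside the
trajectory code, least squares on logs instead of endpoint growth, and
explicit Python-loop sums instead of vectorized weighted means.
"""

from __future__ import annotations

import numpy as np

AGE_EDGES = np.arange(0, 100, 5, dtype=float)  # starts of the 20 groups


def cohort_life_expectancy(m_schedule, dt: float = 1.0 / 365.0, tail_mass: float = 1e-18):
    """Life expectancy at every age-group start by fine-step cohort simulation.

    Survival under the piecewise-constant hazard given by ``m_schedule`` (20
    rates, terminal open interval) is evaluated on a grid of step ``dt`` years
    and integrated by the trapezoidal rule; the grid extends past age 95 until
    the survival mass is negligible. Returns an array of 20 e(a) values.
    """
    m = np.asarray(m_schedule, dtype=float)
    assert m.shape == (20,)
    assert m[-1] > 0, "terminal rate must be positive for a finite horizon"
    horizon = 95.0 + max(5.0, -np.log(tail_mass) / m[-1])
    t = np.arange(0.0, horizon + dt, dt)
    hazard = m[np.minimum((t[:-1] // 5).astype(int), 19)]
    cum = np.concatenate([[0.0], np.cumsum(hazard * np.diff(t))])
    S = np.exp(-cum)
    e = np.empty(20)
    for i, a in enumerate(AGE_EDGES):
        k = int(round(a / dt))
        person_years = np.trapezoid(S[k:], t[k:])
        e[i] = person_years / S[k]
    return e


def quantile_sorted_interp(values, p: float) -> float:
    """Linear-interpolation quantile computed from first principles.

    Sorts, places order statistic j (0-based) at probability j/(n-1), and
    interpolates: the classic "type 7" estimator, written independently of
    numpy's implementation.
    """
    v = sorted(float(x) for x in values)
    n = len(v)
    assert n >= 2
    h = p * (n - 1)
    j = int(np.floor(h))
    if j >= n - 1:
        return v[-1]
    return v[j] + (h - j) * (v[j + 1] - v[j])


def leastsq_log_growth(years, values) -> float:
    """Per-year growth as the OLS slope of log(value) on year."""
    years = np.asarray(years, dtype=float)
    logs = np.log(np.asarray(values, dtype=float))
    slope, _ = np.polyfit(years, logs, 1)
    return float(slope)


def brute_force_weighted_mean(values, weights) -> float:
    """Weighted mean by an explicit Python-loop accumulation."""
    num = 0.0
    den = 0.0
    for x, w in zip(values, weights, strict=True):
        num += float(w) * float(x)
        den += float(w)
    return num / den
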