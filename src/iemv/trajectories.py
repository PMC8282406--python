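"""Scenario mortality-rate paths: base-case, high-performance, low-performance.

The base-case path is the input forecast, untouched. The high- and
low-performance paths converge, by 2030, to the 10th and 90th percentiles of
the 2030 base-case rate distribution of countries in the next higher income
group ("90th / 10th percentile of the lowest mortality rates" read as
percentiles of performance: the high-performance scenario is the
lower-mortality one). Between the 2016 anchor and the 2030 target, rates are
interpolated linearly in log space, i.e. each path is a geometric progression.
Cause paths are built independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    AGE_STARTS,
    CAUSES,
    HIGH_INCOME,
    N_AGE_GROUPS,
    NEXT_HIGHER_GROUP,
    SEXES,
    MortalitySurface,
)

__all__ = [
    "SCENARIOS",
    "COUNTERFACTUAL_SCENARIOS",
    "ZERO_FLOOR",
    "percentile_target",
    "log_linear_path",
    "build_trajectories",
    "TrajectorySet",
]

SCENARIOS = ("base", "high", "low")
COUNTERFACTUAL_SCENARIOS = ("high", "low")

#: Quantile of the reference-group 2030 rate distribution per scenario.
_SCENARIO_QUANTILE = {"high": 0.10, "low": 0.90}

#: Floor applied to exactly-zero rates before the log transform.
ZERO_FLOOR = 1e-10


def percentile_target(reference_rates, scenario: str) -> float:
    """2030 target rate: a percentile of the next-higher group's rate distribution.

    ``high`` maps to the 10th percentile (best-performing tail), ``low`` to the
    90th. Quantiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention), which needs at least two references.
    """
    if scenario not in _SCENARIO_QUANTILE:
        raise ValueError(f"scenario must be one of {COUNTERFACTUAL_SCENARIOS}, got {scenario!r}")
    rates = np.asarray(reference_rates, dtype=float)
    if rates.size == 0:
        raise ValueError(
            "empty reference group: supply an explicit reference rate set "
            "(e.g. high-income countries for UMIC targets)"
        )
    if rates.size < 2:
        raise ValueError(
            f"percentile target needs >= 2 reference rates for interpolation, got {rates.size}"
        )
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("reference rates must be finite and >= 0")
    return float(np.quantile(rates, _SCENARIO_QUANTILE[scenario], method="linear"))


def log_linear_path(rate_2016, target_2030, year, *, anchor_year: int = 2016,
                    horizon: int = 2030, zero_floor: float = ZERO_FLOOR):
    """Rate in ``year`` on the log-linear path from the anchor to the target.

    Both endpoints are floored at ``zero_floor`` before the log transform so
    an exactly-zero rate stays representable; endpoints are reproduced exactly
    (up to that floor). Scalar and array inputs broadcast.
    """
    year = np.asarray(year)
    if np.any(year < anchor_year) or np.any(year > horizon):
        raise ValueError(f"year must lie in [{anchor_year}, {horizon}]")
    r0 = np.maximum(np.asarray(rate_2016, dtype=float), zero_floor)
    r1 = np.maximum(np.asarray(target_2030, dtype=float), zero_floor)
    if np.any(r0 < 0) or np.any(r1 < 0):
        raise ValueError("rates must be >= 0")
    frac = (year - anchor_year) / (horizon - anchor_year)
    out = np.exp(np.log(r0) + frac * (np.log(r1) - np.log(r0)))
    # Endpoints are contractual identities; exp/log round-trip can drift an ulp.
    out = np.where(frac == 0.0, r0, np.where(frac == 1.0, r1, out))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TrajectorySet:
    """Dense scenario rate paths ``rate[country, sex, cause, scenario, year, age]``.

    ``scenarios`` is always ``("base", "high", "low")``; ``years`` runs from the
    anchor (2016) through the horizon (2030). ``targets`` holds the planted
    2030 targets per (country, sex, cause, age) for the two counterfactual
    scenarios.
    """

    rates: np.ndarray = field(repr=False)
    countries: tuple[str, ...]
    years: tuple[int, ...]
    targets: np.ndarray = field(repr=False)  # [country, sex, cause, 2, age], (high, low)
    anchor_year: int = 2016
    horizon: int = 2030

    def scenario_index(self, scenario: str) -> int:
        return SCENARIOS.index(scenario)

    def path(self, country: str, sex: str, cause: str, scenario: str) -> np.ndarray:
        """One (years, ages) rate path."""
        return self.rates[
            self.countries.index(country),
            SEXES.index(sex),
            CAUSES.index(cause),
            self.scenario_index(scenario),
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long format: country, sex, age_start, cause, scenario, year, rate."""
        c, s, d, k, y, a = np.meshgrid(
            np.arange(len(self.countries)),
            np.arange(len(SEXES)),
            np.arange(len(CAUSES)),
            np.arange(len(SCENARIOS)),
            np.arange(len(self.years)),
            np.arange(N_AGE_GROUPS),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "country": np.array(self.countries)[c.ravel()],
                "sex": np.array(SEXES)[s.ravel()],
                "age_start": AGE_STARTS[a.ravel()],
                "cause": np.array(CAUSES)[d.ravel()],
                "scenario": np.array(SCENARIOS)[k.ravel()],
                "year": np.array(self.years)[y.ravel()],
                "rate": self.rates.ravel(),
            }
        )
        return df


def build_trajectories(
    surface: MortalitySurface,
    income_map: dict[str, str],
    *,
    reference_year: int = 2016,
    horizon: int = 2030,
    zero_floor: float = ZERO_FLOOR,
    reference_surface: MortalitySurface | None = None,
) -> TrajectorySet:
    """Assemble base/high/low paths for every analysis country-sex-cause-age cell.

    ``income_map`` assigns every country in ``surface`` an income group; only
    LIC/LMIC/UMIC countries get scenario paths, while countries mapped to the
    high-income label serve as the UMIC reference set. ``reference_surface``
    may supply the reference rates from a separate table instead (same schema).
    Reference targets are quantiles over one pooled 2030 base-case rate per
    reference country, so paths are invariant to country order.
    """
    ref_src = reference_surface if reference_surface is not None else surface
    ref_arr, ref_countries, ref_years = ref_src.to_array()
    if horizon not in ref_years:
        raise ValueError(f"reference surface lacks year {horizon}")

    arr, countries, years = surface.to_array()
    if reference_year not in years:
        raise ValueError(f"surface lacks the anchor year {reference_year}")
    missing_years = [y for y in range(reference_year, horizon + 1) if y not in years]
    if missing_years:
        raise ValueError(f"surface lacks forecast years {missing_years}")

    ref_income = {c: income_map.get(c) for c in ref_countries}
    analysis = [c for c in countries if income_map.get(c) in NEXT_HIGHER_GROUP]

    # Pooled 2030 base-case rates of each income group, for use as references.
    y2030_ref = ref_years.index(horizon)
    group_members: dict[str, list[int]] = {}
    for i, c in enumerate(ref_countries):
        group_members.setdefault(ref_income.get(c), []).append(i)

    no_reference = [
        c for c in analysis if len(group_members.get(NEXT_HIGHER_GROUP[income_map[c]], [])) < 2
    ]
    if no_reference:
        needed = sorted({NEXT_HIGHER_GROUP[income_map[c]] for c in no_reference})
        raise ValueError(
            f"countries {no_reference} have no usable next-higher income reference group "
            f"(need >= 2 countries in {needed}; for UMICs supply a high-income reference surface)"
        )

    # Targets per income group: quantiles over reference countries, per (sex, cause, age).
    group_targets: dict[str, np.ndarray] = {}  # [sex, cause, 2, age]
    for group in {income_map[c] for c in analysis}:
        ref_idx = group_members[NEXT_HIGHER_GROUP[group]]
        pool = ref_arr[ref_idx, :, :, y2030_ref, :]  # [ref_country, sex, cause, age]
        high = np.quantile(pool, _SCENARIO_QUANTILE["high"], axis=0, method="linear")
        low = np.quantile(pool, _SCENARIO_QUANTILE["low"], axis=0, method="linear")
        group_targets[group] = np.stack([high, low], axis=2)

    path_years = tuple(range(reference_year, horizon + 1))
    year_pos = [years.index(y) for y in path_years]
    n_c = len(analysis)
    rates = np.empty((n_c, len(SEXES), len(CAUSES), len(SCENARIOS), len(path_years), N_AGE_GROUPS))
    targets = np.empty((n_c, len(SEXES), len(CAUSES), 2, N_AGE_GROUPS))

    frac = (np.array(path_years) - reference_year) / (horizon - reference_year)
    for i, c in enumerate(analysis):
        ci = countries.index(c)
        base = arr[ci][:, :, year_pos, :]  # [sex, cause, year, age]
        rates[i, :, :, 0] = base
        anchor = np.maximum(base[:, :, 0, :], zero_floor)  # 2016 observed
        tgt = np.maximum(group_targets[income_map[c]], zero_floor)  # [sex, cause, 2, age]
        targets[i] = group_targets[income_map[c]]
        log_anchor = np.log(anchor)[:, :, None, :]
        log_tgt = np.log(tgt)
        for k in (0, 1):  # high, low
            rates[i, :, :, k + 1] = np.exp(
                log_anchor + frac[None, None, :, None] * (log_tgt[:, :, k, None, :] - log_anchor)
            )
            # Anchor and target are contractual identities, not limits.
            rates[i, :, :, k + 1, 0, :] = anchor
            rates[i, :, :, k + 1, -1, :] = tgt[:, :, k, :]

    return TrajectorySet(
        rates=rates,
        countries=tuple(analysis),
        years=path_years,
        targets=targets,
        anchor_year=reference_year,
        horizon=horizon,
    )
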