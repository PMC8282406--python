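"""VSL scaling, GNI projection, and the value of a standardized mortality unit.

The country-year value of a statistical life is transferred from a US base
value by income scaling, VSL_{c,y} = VSL_base * (I_{c,y} / I_base)^epsilon,
with the income ratio optionally capped (no country valued above the base) or
fixed outright (the sensitivity scenarios fix the base-to-country ratio at 160
or 100, i.e. an income ratio of 1/160 or 1/100). GNI per capita beyond the
last observed year is projected at the income group's mean exponential growth
rate fitted on 2010-2017 window endpoints. The VSMU at the reference age group
[35, 40) equals VSL times the SMU risk size (1e-4); at other ages it scales
with the ratio of remaining life expectancies, so with a declining e schedule
deaths at younger ages are valued more.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .core_model import GniSeries
from .demography import SMU_SIZE

__all__ = [
    "ValuationParams",
    "load_scenario",
    "scenario_names",
    "fit_growth_rate",
    "group_mean_growth",
    "project_gni",
    "GniProjection",
    "vsl_for",
    "vsmu_reference",
    "vsmu_at_age",
]

REFERENCE_AGE_START = 35
GROWTH_WINDOW = (2010, 2017)
PROJECTION_YEARS = tuple(range(2018, 2031))


@dataclass(frozen=True)
class ValuationParams:
    """Parameters of the VSL transfer and VSMU construction.

    vsl_base
        US value of a statistical life, 2015 USD.
    i_base
        US GNI per capita, 2015 USD.
    epsilon
        VSL income elasticity (percent change in VSL per percent change in
        income). Defaults to 1.0, the conventional cross-country transfer
        value; always configurable.
    ratio_ceiling
        Upper bound on the income ratio I_c / I_base (1.0 means no country is
        valued above the US base).
    fixed_ratio
        If set (e.g. 160 or 100), overrides the income ratio with
        1 / fixed_ratio regardless of country income.
    smu_size
        Risk-of-death change represented by one SMU; fixed at 1e-4.
    reference_age_start
        Start of the reference age group for VSMU age scaling; fixed at 35.
    """

    vsl_base: float = 9_400_000.0
    i_base: float = 57_900.0
    epsilon: float = 1.0
    ratio_ceiling: float = 1.0
    fixed_ratio: float | None = None
    smu_size: float = SMU_SIZE
    reference_age_start: int = REFERENCE_AGE_START

    def __post_init__(self) -> None:
        if self.vsl_base <= 0 or self.i_base <= 0:
            raise ValueError("vsl_base and i_base must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.ratio_ceiling <= 0:
            raise ValueError("ratio_ceiling must be positive")
        if self.fixed_ratio is not None and self.fixed_ratio <= 0:
            raise ValueError("fixed_ratio must be positive when set")
        if not math.isclose(self.smu_size, SMU_SIZE):
            raise ValueError(f"smu_size is fixed at {SMU_SIZE} (one SMU = 1e-4 risk change)")
        if self.reference_age_start != REFERENCE_AGE_START:
            raise ValueError(f"reference age group is fixed at [{REFERENCE_AGE_START}, 40)")


def _scenario_table() -> dict:
    text = importlib.resources.files("iemv").joinpath("configs/scenarios.yaml").read_text()
    return yaml.safe_load(text)


def scenario_names() -> list[str]:
    return list(_scenario_table())


def load_scenario(name: str, **overrides) -> ValuationParams:
    """Load one of the shipped valuation scenarios as :class:`ValuationParams`.

    ``primary`` is the default analysis; ``sensitivity_1`` raises the
    elasticity to 1.5; ``sensitivity_2`` and ``sensitivity_3`` fix the
    base-to-country income ratio at 160 and 100 with unit elasticity. Keyword
    overrides replace individual fields.
    """
    table = _scenario_table()
    if name not in table:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(table)}")
    params = ValuationParams(**table[name])
    return replace(params, **overrides) if overrides else params


def fit_growth_rate(
    gni: GniSeries | pd.DataFrame,
    country: str,
    window: tuple[int, int] = GROWTH_WINDOW,
) -> float:
    """Per-year exponential (log) growth rate from the window endpoints.

    r = ln(I_end / I_start) / (end - start) over observations inside
    ``window``. If the series starts later than the window, the longest
    available sub-window ending at the window's last year is used (the reader
    warns about this at load time).
    """
    frame = gni.frame if isinstance(gni, GniSeries) else gni
    sub = frame[(frame["country"] == country) & frame["year"].between(*window)]
    if len(sub) < 2:
        raise ValueError(
            f"cannot fit growth for {country}: fewer than 2 GNI observations in {window}"
        )
    sub = sub.sort_values("year")
    y0, y1 = int(sub["year"].iloc[0]), int(sub["year"].iloc[-1])
    i0, i1 = float(sub["gni_pc"].iloc[0]), float(sub["gni_pc"].iloc[-1])
    return math.log(i1 / i0) / (y1 - y0)


def group_mean_growth(
    gni: GniSeries,
    income_map: dict[str, str],
    window: tuple[int, int] = GROWTH_WINDOW,
) -> dict[str, float]:
    """Mean fitted growth rate within each income group (unweighted over countries)."""
    rates: dict[str, list[float]] = {}
    for country in gni.countries:
        group = income_map.get(country)
        if group is None:
            continue
        rates.setdefault(group, []).append(fit_growth_rate(gni, country, window))
    return {g: float(np.mean(v)) for g, v in sorted(rates.items())}


@dataclass(frozen=True)
class GniProjection:
    """Observed-plus-projected GNI per capita and the group growth rates used."""

    frame: pd.DataFrame  # country, year, gni_pc (anchor year + projected years)
    group_growth: dict[str, float]
    anchor_year: int

    def array(self, countries: list[str], years: list[int]) -> np.ndarray:
        wide = self.frame.pivot(index="country", columns="year", values="gni_pc")
        return wide.loc[countries, years].to_numpy()


def project_gni(
    gni: GniSeries,
    group_growth: dict[str, float],
    income_map: dict[str, str],
    *,
    anchor_year: int = 2017,
    years: tuple[int, ...] = PROJECTION_YEARS,
) -> GniProjection:
    """Project each country's GNI per capita forward from its last observed
    anchor at its income group's mean growth rate:
    I_{c,y} = I_{c,anchor} * exp(r_group * (y - anchor)).
    """
    rows = []
    for country in gni.countries:
        group = income_map.get(country)
        if group is None or group not in group_growth:
            continue
        try:
            anchor = gni.value(country, anchor_year)
        except KeyError:
            raise ValueError(
                f"country {country} lacks the {anchor_year} GNI anchor and must be excluded"
            ) from None
        r = group_growth[group]
        rows.append({"country": country, "year": anchor_year, "gni_pc": anchor})
        for y in years:
            rows.append(
                {"country": country, "year": y, "gni_pc": anchor * math.exp(r * (y - anchor_year))}
            )
    frame = pd.DataFrame(rows).sort_values(["country", "year"]).reset_index(drop=True)
    return GniProjection(frame=frame, group_growth=dict(group_growth), anchor_year=anchor_year)


def vsl_for(gni_pc, params: ValuationParams):
    """Country-year VSL by income scaling of the base VSL.

    The income ratio is 1/fixed_ratio when a fixed ratio is set, otherwise
    min(gni_pc / i_base, ratio_ceiling). Broadcasts over arrays of gni_pc.
    """
    gni_pc = np.asarray(gni_pc, dtype=float)
    if np.any(gni_pc <= 0):
        raise ValueError("gni_pc must be positive")
    if params.fixed_ratio is not None:
        ratio = np.full_like(gni_pc, 1.0 / params.fixed_ratio)
    else:
        ratio = np.minimum(gni_pc / params.i_base, params.ratio_ceiling)
    out = params.vsl_base * ratio**params.epsilon
    return float(out) if out.ndim == 0 else out


def vsmu_reference(vsl, params: ValuationParams):
    """VSMU at the reference age group [35, 40): VSL per 1e-4 risk change."""
    vsl = np.asarray(vsl, dtype=float)
    if np.any(vsl <= 0):
        raise ValueError("vsl must be positive")
    out = vsl * params.smu_size
    return float(out) if out.ndim == 0 else out


def vsmu_at_age(vsmu_ref, e_a, e_ref):
    """Age-scale the reference VSMU by the life-expectancy ratio e(a) / e(35)."""
    e_ref = np.asarray(e_ref, dtype=float)
    if np.any(e_ref <= 0):
        raise ValueError("reference-age life expectancy must be positive")
    out = np.asarray(vsmu_ref, dtype=float) * np.asarray(e_a, dtype=float) / e_ref
    return float(out) if out.ndim == 0 else out
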