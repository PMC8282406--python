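"""Synthetic country panels with planted ground truth.

Emulates the three external inputs the pipeline consumes — a cause-sex-age
mortality surface (GBD-Foresight-like forecast export), a country-year GNI
per capita series (WDI-like), and age-structured population projections for
2020/2025/2030 (WPP-like) — for a world of LIC/LMIC/UMIC analysis countries
plus a high-income auxiliary block that serves as the UMIC reference group.

Mortality is log-level + log-linear in age + linear-in-year drift + optional
log-scale noise: Gompertz-like age slopes are positive for the adult NCD
causes and negative for the communicable and maternal/neonatal/nutritional
block, so the "younger ages valued more" mechanics and the age-pattern
narrative are both exercised. All randomness flows from a single seed through
one independent stream per table, so regenerating one table never perturbs
another, and identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import (
    AGE_STARTS,
    CAUSES,
    INCOME_BANDS,
    N_AGE_GROUPS,
    SEXES,
    GniSeries,
    MortalitySurface,
    PopulationTable,
)

__all__ = ["SynthConfig", "CauseParams", "synth_world", "degrade_panel", "bundled_fixture"]

GROUPS = ("LIC", "LMIC", "UMIC", "AUX")

#: Log-level offset per income group: mortality declines with income.
_GROUP_OFFSET = {"LIC": 0.0, "LMIC": -0.25, "UMIC": -0.5, "AUX": -0.75}

#: GNI anchor bands at 2016 (USD): inside the classification band with margin
#: so noise on non-anchor years can never flip a country's group.
_DEFAULT_GNI_ANCHORS = {
    "LIC": (620.0, 985.0),
    "LMIC": (1100.0, 3900.0),
    "UMIC": (4100.0, 12000.0),
    "AUX": (20000.0, 45000.0),
}

#: Mean per-year log growth in GNI per capita by income group.
_DEFAULT_GROWTH = {"LIC": 0.025, "LMIC": 0.030, "UMIC": 0.025, "AUX": 0.015}


@dataclass(frozen=True)
class CauseParams:
    """Planted mortality model for one cause: log-rate at age 35, log slope
    per decade of age, and per-year log drift."""

    log_level_35: float
    age_slope_per_decade: float
    year_trend: float


_DEFAULT_CAUSE_PARAMS: dict[str, CauseParams] = {
    "neoplasms": CauseParams(np.log(1.2e-3), 0.55, -0.010),
    "cardiovascular": CauseParams(np.log(1.5e-3), 0.85, -0.012),
    "chronic_respiratory": CauseParams(np.log(4e-4), 0.80, -0.010),
    "diabetes_blood_urogenital_endocrine": CauseParams(np.log(6e-4), 0.65, -0.008),
    "mental": CauseParams(np.log(2e-4), 0.30, -0.005),
    "injuries": CauseParams(np.log(8e-4), 0.10, -0.008),
    "communicable": CauseParams(np.log(2.5e-3), -0.35, -0.030),
    "maternal_neonatal_nutritional": CauseParams(np.log(1.5e-3), -0.55, -0.040),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic world.

    Defaults: 10 countries per analysis income group plus a 4-country
    high-income auxiliary block, years 2010-2030, group growth rates in the
    0.015-0.03/yr range anchored inside the 2016 classification bands, and a
    log-scale noise sd of 0.02 on mortality cells and non-anchor GNI years.
    """

    seed: int = 17
    n_countries_per_group: int = 10
    n_aux_countries: int = 4
    years: tuple[int, int] = (2010, 2030)
    baseline_mortality_by_cause: dict[str, CauseParams] = field(
        default_factory=lambda: dict(_DEFAULT_CAUSE_PARAMS)
    )
    cause_trend_scale: float = 1.0
    gni_anchor_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GNI_ANCHORS)
    )
    planted_growth: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GROWTH))
    noise_sd: float = 0.02
    country_spread_sd: float = 0.15
    male_log_offset: float = 0.08

    def __post_init__(self) -> None:
        if self.n_countries_per_group < 2:
            raise ValueError(
                "need at least 2 countries per group: percentile targets are "
                "undefined for a single reference country"
            )
        if self.n_aux_countries < 2:
            raise ValueError("need at least 2 auxiliary (high-income) reference countries")
        if self.noise_sd < 0 or self.country_spread_sd < 0:
            raise ValueError("noise parameters must be >= 0")


_GROUP_CODE = {"LIC": "LIC", "LMIC": "LMC", "UMIC": "UMC", "AUX": "AUX"}


def _country_codes(config: SynthConfig) -> dict[str, list[str]]:
    out = {}
    for g in GROUPS:
        n = config.n_aux_countries if g == "AUX" else config.n_countries_per_group
        out[g] = [f"{_GROUP_CODE[g]}{i:02d}" for i in range(1, n + 1)]
    return out


def synth_world(config: SynthConfig = SynthConfig()):
    """Generate (MortalitySurface, GniSeries, PopulationTable, ground_truth).

    ``ground_truth`` records everything planted: country->group membership,
    the group growth rates, per-country realized GNI anchors, the country
    random effects, and the realized 2030 base-case rate array (with labels)
    from which percentile targets can be recomputed independently.
    """
    codes = _country_codes(config)
    countries = [c for g in GROUPS for c in codes[g]]
    block_of = {c: g for g in GROUPS for c in codes[g]}
    # the auxiliary block plays the high-income role downstream
    group_of = {c: ("HIC" if g == "AUX" else g) for c, g in block_of.items()}
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))

    root = np.random.SeedSequence(config.seed)
    mort_rng, gni_rng, pop_rng = (np.random.default_rng(s) for s in root.spawn(3))

    # --- mortality surface ---------------------------------------------------
    n_c, n_s, n_d, n_y, n_a = len(countries), len(SEXES), len(CAUSES), len(years), N_AGE_GROUPS
    age_mid = AGE_STARTS + 2.5
    age_mid[-1] = 100.0  # nominal midpoint of the open interval
    country_effect = mort_rng.normal(0.0, config.country_spread_sd, size=n_c)
    noise = (
        mort_rng.normal(0.0, config.noise_sd, size=(n_c, n_s, n_d, n_y, n_a))
        if config.noise_sd > 0
        else np.zeros((n_c, n_s, n_d, n_y, n_a))
    )

    log_rate = np.empty((n_c, n_s, n_d, n_y, n_a))
    yr = np.array(years) - 2016
    for di, cause in enumerate(CAUSES):
        p = config.baseline_mortality_by_cause[cause]
        age_term = p.log_level_35 + p.age_slope_per_decade * (age_mid - 37.5) / 10.0
        trend = config.cause_trend_scale * p.year_trend * yr
        log_rate[:, :, di] = age_term[None, None, None, :] + trend[None, None, :, None]
    log_rate += country_effect[:, None, None, None, None]
    log_rate[:, 1] += config.male_log_offset  # males
    for g in GROUPS:
        idx = [countries.index(c) for c in codes[g]]
        log_rate[idx] += _GROUP_OFFSET[g]
    log_rate += noise
    rate = np.exp(log_rate)

    c, s, d, y, a = np.meshgrid(
        np.arange(n_c), np.arange(n_s), np.arange(n_d), np.arange(n_y), np.arange(n_a),
        indexing="ij",
    )
    mort_df = pd.DataFrame(
        {
            "country": np.array(countries)[c.ravel()],
            "sex": np.array(SEXES)[s.ravel()],
            "cause": np.array(CAUSES)[d.ravel()],
            "year": np.array(years)[y.ravel()],
            "age_group_start": AGE_STARTS[a.ravel()],
            "rate": rate.ravel(),
        }
    )
    surface = MortalitySurface.from_frame(mort_df)

    # --- GNI series ----------------------------------------------------------
    gni_rows = []
    anchors = {}
    gni_years = [yy for yy in years if yy <= 2017]
    for ci, country in enumerate(countries):
        g = block_of[country]
        lo, hi = config.gni_anchor_range[g]
        anchor = float(gni_rng.uniform(lo, hi))
        anchors[country] = anchor
        r = config.planted_growth[g]
        eps = gni_rng.normal(0.0, config.noise_sd, size=len(gni_years)) if config.noise_sd > 0 else np.zeros(len(gni_years))
        for yi, yy in enumerate(gni_years):
            value = anchor * np.exp(r * (yy - 2016))
            if yy != 2016:  # the anchor year is noise-free so classification is exact
                value *= np.exp(eps[yi])
            gni_rows.append({"country": country, "year": yy, "gni_pc": value})
    gni = GniSeries.from_frame(pd.DataFrame(gni_rows))

    # --- population ----------------------------------------------------------
    pop_rows = []
    age_struct = np.exp(-0.03 * (AGE_STARTS + 2.5))
    age_struct /= age_struct.sum()
    for country in countries:
        base = float(pop_rng.lognormal(mean=np.log(2e6), sigma=0.5))
        sex_share = {"F": 0.5, "M": 0.5}
        for yy in (2020, 2025, 2030):
            growth = np.exp(0.01 * (yy - 2020))
            for sex in SEXES:
                counts = base * sex_share[sex] * growth * age_struct
                for ai, a0 in enumerate(AGE_STARTS):
                    pop_rows.append(
                        {
                            "country": country,
                            "sex": sex,
                            "age_group_start": int(a0),
                            "year": yy,
                            "count": float(counts[ai]),
                        }
                    )
    population = PopulationTable.from_frame(pd.DataFrame(pop_rows))

    y2030 = years.index(2030)
    ground_truth = {
        "config": config,
        "group_of": group_of,
        "countries_by_group": codes,
        "planted_growth": dict(config.planted_growth),
        "gni_anchors": anchors,
        "country_effect": dict(zip(countries, country_effect)),
        "rates_2030": rate[:, :, :, y2030, :],  # [country, sex, cause, age]
        "rate_labels": {"countries": countries, "sexes": list(SEXES), "causes": list(CAUSES)},
    }
    return surface, gni, population, ground_truth


def degrade_panel(panel, drop_spec: dict[str, list[str]]):
    """Deterministically remove whole countries from named tables.

    ``panel`` is the (surface, gni, population) triple (a trailing
    ground-truth element is passed through untouched); ``drop_spec`` maps
    table names ("mortality", "gni", "population") to country lists. Naming a
    country absent from that table is an error. An empty spec is the identity.
    """
    surface, gni, population = panel[0], panel[1], panel[2]
    rest = panel[3:]
    valid = {"mortality", "gni", "population"}
    unknown = set(drop_spec) - valid
    if unknown:
        raise ValueError(f"unknown table(s) in drop_spec: {sorted(unknown)}; valid: {sorted(valid)}")
    present = {"mortality": set(surface.countries), "gni": set(gni.countries),
               "population": set(population.countries)}
    for table, drops in drop_spec.items():
        absent = sorted(set(drops) - present[table])
        if absent:
            raise ValueError(f"drop_spec names strata absent from {table}: {absent}")
    if drops := drop_spec.get("mortality"):
        surface = surface.restrict([c for c in surface.countries if c not in drops])
    if drops := drop_spec.get("gni"):
        keep = [c for c in gni.countries if c not in drops]
        gni = GniSeries(gni.frame[gni.frame["country"].isin(keep)].reset_index(drop=True))
    if drops := drop_spec.get("population"):
        keep = [c for c in population.countries if c not in drops]
        population = PopulationTable(
            population.frame[population.frame["country"].isin(keep)].reset_index(drop=True)
        )
    return (surface, gni, population, *rest)


def bundled_fixture():
    """The small documentation fixture: 3 countries per group, seed 17.

    Regenerated deterministically on demand (same bytes every call) rather
    than stored, so examples and doctests always agree with the generator.
    """
    return synth_world(replace(SynthConfig(), seed=17, n_countries_per_group=3, n_aux_countries=3))
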