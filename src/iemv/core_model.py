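"""Canonical data model: age grid, cause categories, income groups, table readers.

All monetary fields throughout the package are constant 2015 USD, undiscounted.
Countries are identified by opaque ISO3-like strings; no name matching is
attempted. Mortality rates are deaths per person-year on a fixed abridged age
grid of twenty five-year groups with a terminal open interval at 95+.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "AGE_GROUPS",
    "AGE_STARTS",
    "N_AGE_GROUPS",
    "CAUSES",
    "DEFAULT_CAUSE_ALIASES",
    "IncomeBand",
    "INCOME_BANDS",
    "HIGH_INCOME",
    "classify_income_group",
    "MortalitySurface",
    "GniSeries",
    "PopulationTable",
    "read_mortality_table",
    "read_gni_table",
    "read_population_table",
    "validate_panel",
    "PanelValidation",
    "FormatError",
    "ValidationError",
]

N_AGE_GROUPS = 20
AGE_STARTS: np.ndarray = np.arange(0, 100, 5)

POPULATION_YEARS = (2020, 2025, 2030)

SEXES = ("F", "M")


@dataclass(frozen=True)
class AgeGroup:
    """One interval [start, start + width) of the abridged age grid.

    The final group (index 19, starting at 95) is open-ended; its nominal
    width is irrelevant to any computation and recorded as ``inf``.
    """

    index: int
    start: int
    width: float
    open_ended: bool

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_AGE_GROUPS:
            raise ValueError(f"age group index out of range: {self.index}")
        if self.start != 5 * self.index:
            raise ValueError("age group start must equal 5 * index")


AGE_GROUPS: tuple[AgeGroup, ...] = tuple(
    AgeGroup(i, 5 * i, np.inf if i == N_AGE_GROUPS - 1 else 5.0, i == N_AGE_GROUPS - 1)
    for i in range(N_AGE_GROUPS)
)

# The eight aggregated cause-of-death categories, fixed labels.
CAUSES: tuple[str, ...] = (
    "neoplasms",
    "cardiovascular",
    "chronic_respiratory",
    "diabetes_blood_urogenital_endocrine",
    "mental",
    "injuries",
    "communicable",
    "maternal_neonatal_nutritional",
)

# User-extensible aliases for cause labels as they appear in external exports.
DEFAULT_CAUSE_ALIASES: dict[str, str] = {
    "Neoplasms": "neoplasms",
    "Cardiovascular diseases": "cardiovascular",
    "CVDs": "cardiovascular",
    "Chronic respiratory diseases": "chronic_respiratory",
    "Diabetes, blood, urogenital, and other endocrine diseases": "diabetes_blood_urogenital_endocrine",
    "Diabetes": "diabetes_blood_urogenital_endocrine",
    "Mental disorders": "mental",
    "Injuries": "injuries",
    "Communicable diseases": "communicable",
    "CDs": "communicable",
    "Maternal, neonatal, and nutritional diseases": "maternal_neonatal_nutritional",
}


class FormatError(ValueError):
    """A table does not conform to the expected CSV schema."""


class ValidationError(ValueError):
    """A table parses but violates a domain invariant."""


@dataclass(frozen=True)
class IncomeBand:
    label: str
    gni_lower: float
    gni_upper: float


# 2016 World Bank classification thresholds, USD per capita.
INCOME_BANDS: tuple[IncomeBand, ...] = (
    IncomeBand("LIC", 0.0, 1005.0),
    IncomeBand("LMIC", 1006.0, 3995.0),
    IncomeBand("UMIC", 3996.0, 12235.0),
)

#: Sentinel label for countries above the UMIC band: out of analysis scope but
#: usable as the reference group for UMIC trajectory targets.
HIGH_INCOME = "HIC"

INCOME_ORDER = ("LIC", "LMIC", "UMIC", HIGH_INCOME)
NEXT_HIGHER_GROUP = {"LIC": "LMIC", "LMIC": "UMIC", "UMIC": HIGH_INCOME}


def classify_income_group(gni_pc_2016: float) -> str:
    """Classify a country by its 2016 GNI per capita (USD).

    Returns ``"LIC"``, ``"LMIC"`` or ``"UMIC"`` per the fixed bands; values
    above the UMIC ceiling return :data:`HIGH_INCOME` ("out of scope (high
    income)") rather than raising, so high-income reference countries can ride
    along in a panel.
    """
    if not np.isfinite(gni_pc_2016) or gni_pc_2016 <= 0:
        raise ValueError(f"GNI per capita must be positive, got {gni_pc_2016!r}")
    for band in INCOME_BANDS:
        if gni_pc_2016 <= band.gni_upper:
            return band.label
    return HIGH_INCOME


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")


def _check_complete_grid(df: pd.DataFrame, keys: list[str], what: str) -> None:
    """Every combination of the observed key levels must be present exactly once."""
    expected = 1
    for k in keys:
        expected *= df[k].nunique()
    if df.duplicated(subset=keys).any():
        dups = df[df.duplicated(subset=keys, keep=False)].head(5)
        raise ValidationError(f"{what}: duplicate strata, e.g.\n{dups[keys].to_string(index=False)}")
    if len(df) != expected:
        # Identify a few missing strata for the error message.
        idx = pd.MultiIndex.from_product([sorted(df[k].unique()) for k in keys], names=keys)
        have = pd.MultiIndex.from_frame(df[keys])
        missing = idx.difference(have)
        sample = list(missing[:5])
        raise ValidationError(
            f"{what}: incomplete grid; expected {expected} rows over {keys}, got {len(df)}. "
            f"Missing strata include {sample}"
        )


@dataclass(frozen=True)
class MortalitySurface:
    """Cause-sex-age-country-year mortality rates on the fixed 20-bin age grid.

    Wraps a long-format frame with columns
    ``country, sex, cause, year, age_start, rate`` sorted canonically, and
    guarantees a complete grid with finite non-negative rates.
    """

    frame: pd.DataFrame = field(repr=False)

    KEYS = ["country", "sex", "cause", "year", "age_start"]
    COLUMNS = ("country", "sex", "cause", "year", "age_group_start", "rate")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, aliases: dict[str, str] | None = None) -> "MortalitySurface":
        _require_columns(df, cls.COLUMNS, "mortality table")
        df = df.rename(columns={"age_group_start": "age_start"}).copy()
        alias_map = dict(DEFAULT_CAUSE_ALIASES)
        if aliases:
            alias_map.update(aliases)
        df["cause"] = df["cause"].map(lambda c: alias_map.get(c, c))
        unknown = sorted(set(df["cause"]) - set(CAUSES))
        if unknown:
            raise ValidationError(
                f"mortality table: unknown cause label(s) {unknown}; extend the alias table or fix the input"
            )
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise ValidationError(f"mortality table: sex must be one of {SEXES}, got {bad_sex}")
        df["year"] = df["year"].astype(int)
        df["age_start"] = df["age_start"].astype(int)
        df["rate"] = df["rate"].astype(float)
        bad_age = sorted(set(df["age_start"]) - set(AGE_STARTS.tolist()))
        if bad_age:
            raise ValidationError(
                f"mortality table: age_group_start values {bad_age} are not on the fixed 5-year grid "
                f"0..95; inputs on other grids are rejected, not re-binned"
            )
        if df["age_start"].nunique() != N_AGE_GROUPS:
            raise ValidationError(
                f"mortality table: expected all {N_AGE_GROUPS} age groups, found {df['age_start'].nunique()}"
            )
        bad = df[~np.isfinite(df["rate"]) | (df["rate"] < 0)]
        if len(bad):
            raise ValidationError(
                "mortality table: rates must be finite and >= 0; offending rows:\n"
                + bad.head(10).to_string(index=False)
            )
        _check_complete_grid(df, cls.KEYS, "mortality table")
        df = df.sort_values(cls.KEYS, kind="mergesort").reset_index(drop=True)
        return cls(df)

    @property
    def countries(self) -> list[str]:
        return sorted(self.frame["country"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    def to_array(self) -> tuple[np.ndarray, list[str], list[int]]:
        """Dense array view ``rate[country, sex, cause, year, age]`` plus labels.

        Sexes are ordered (F, M) and causes per :data:`CAUSES`.
        """
        countries, years = self.countries, self.years
        shape = (len(countries), len(SEXES), len(CAUSES), len(years), N_AGE_GROUPS)
        df = self.frame
        c_idx = df["country"].map({c: i for i, c in enumerate(countries)}).to_numpy()
        s_idx = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
        d_idx = df["cause"].map({d: i for i, d in enumerate(CAUSES)}).to_numpy()
        y_idx = df["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        a_idx = (df["age_start"].to_numpy() // 5).astype(int)
        arr = np.empty(shape)
        arr[c_idx, s_idx, d_idx, y_idx, a_idx] = df["rate"].to_numpy()
        return arr, countries, years

    def restrict(self, countries: list[str]) -> "MortalitySurface":
        return MortalitySurface(
            self.frame[self.frame["country"].isin(countries)].reset_index(drop=True)
        )

    def write_csv(self, path) -> None:
        out = self.frame.rename(columns={"age_start": "age_group_start"})
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class GniSeries:
    """Country-year GNI per capita, constant 2015 USD."""

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("country", "year", "gni_pc")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, growth_window: tuple[int, int] = (2010, 2017)) -> "GniSeries":
        _require_columns(df, cls.COLUMNS, "GNI table")
        df = df[list(cls.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["gni_pc"] = df["gni_pc"].astype(float)
        bad = df[~np.isfinite(df["gni_pc"]) | (df["gni_pc"] <= 0)]
        if len(bad):
            raise ValidationError(
                "GNI table: gni_pc must be finite and > 0; offending rows:\n"
                + bad.head(10).to_string(index=False)
            )
        if df.duplicated(subset=["country", "year"]).any():
            raise ValidationError("GNI table: duplicate (country, year) rows")
        lo, hi = growth_window
        for country, sub in df.groupby("country"):
            years = set(sub["year"])
            window = [y for y in range(lo, hi + 1) if y in years]
            if window and min(window) > lo:
                warnings.warn(
                    f"GNI series for {country} starts at {min(window)} (> {lo}); "
                    f"growth fitting will use the shorter window [{min(window)}, {hi}]",
                    stacklevel=2,
                )
        df = df.sort_values(["country", "year"], kind="mergesort").reset_index(drop=True)
        return cls(df)

    @property
    def countries(self) -> list[str]:
        return sorted(self.frame["country"].unique())

    def value(self, country: str, year: int) -> float:
        sub = self.frame[(self.frame["country"] == country) & (self.frame["year"] == year)]
        if sub.empty:
            raise KeyError(f"no GNI observation for {country} in {year}")
        return float(sub["gni_pc"].iloc[0])

    def restrict(self, countries: list[str]) -> "GniSeries":
        return GniSeries(self.frame[self.frame["country"].isin(countries)].reset_index(drop=True))

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class PopulationTable:
    """Country-sex-age population counts for the reporting years 2020/2025/2030."""

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("country", "sex", "age_group_start", "year", "count")
    KEYS = ["country", "sex", "age_start", "year"]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationTable":
        _require_columns(df, cls.COLUMNS, "population table")
        df = df.rename(columns={"age_group_start": "age_start"}).copy()
        df["year"] = df["year"].astype(int)
        df["age_start"] = df["age_start"].astype(int)
        df["count"] = df["count"].astype(float)
        bad_year = sorted(set(df["year"]) - set(POPULATION_YEARS))
        if bad_year:
            raise ValidationError(
                f"population table: projections are accepted only for years {POPULATION_YEARS}; "
                f"got rows for {bad_year}"
            )
        bad = df[~np.isfinite(df["count"]) | (df["count"] < 0)]
        if len(bad):
            raise ValidationError(
                "population table: counts must be finite and >= 0; offending rows:\n"
                + bad.head(10).to_string(index=False)
            )
        _check_complete_grid(df, cls.KEYS, "population table")
        if df["year"].nunique() != len(POPULATION_YEARS):
            raise ValidationError(
                f"population table: all three years {POPULATION_YEARS} are required, "
                f"found {sorted(df['year'].unique())}"
            )
        df = df.sort_values(cls.KEYS, kind="mergesort").reset_index(drop=True)
        return cls(df)

    @property
    def countries(self) -> list[str]:
        return sorted(self.frame["country"].unique())

    def weights(self, year: int) -> pd.DataFrame:
        """Counts for one reporting year, columns country/sex/age_start/count."""
        sub = self.frame[self.frame["year"] == year]
        return sub[["country", "sex", "age_start", "count"]].reset_index(drop=True)

    def restrict(self, countries: list[str]) -> "PopulationTable":
        return PopulationTable(
            self.frame[self.frame["country"].isin(countries)].reset_index(drop=True)
        )

    def write_csv(self, path) -> None:
        out = self.frame.rename(columns={"age_start": "age_group_start"})
        out.to_csv(path, index=False)


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_mortality_table(path, aliases: dict[str, str] | None = None) -> MortalitySurface:
    """Read a GBD-Foresight-style long CSV into a validated :class:`MortalitySurface`."""
    return MortalitySurface.from_frame(_read_csv(path), aliases=aliases)


def read_gni_table(path, growth_window: tuple[int, int] = (2010, 2017)) -> GniSeries:
    return GniSeries.from_frame(_read_csv(path), growth_window=growth_window)


def read_population_table(path) -> PopulationTable:
    return PopulationTable.from_frame(_read_csv(path))


@dataclass(frozen=True)
class PanelValidation:
    """Outcome of joint validation of the three input tables."""

    included: tuple[str, ...]
    excluded: tuple[str, ...]
    reasons: dict[str, str]

    def __iter__(self):  # allow `list(validate_panel(...))` per the op contract
        return iter(self.excluded)


def validate_panel(
    surface: MortalitySurface,
    gni: GniSeries,
    population: PopulationTable,
    required_span: tuple[int, int] = (2016, 2030),
    anchor_year: int = 2017,
) -> PanelValidation:
    """Exclude countries missing any of the three inputs; report who and why.

    A country is retained only if it has mortality rates spanning
    ``required_span``, a GNI observation at ``anchor_year`` (the projection
    anchor) plus at least one earlier year for growth fitting, and population
    counts for all three reporting years. Mirrors the published exclusion rule
    for countries lacking GNI, population, or mortality estimates.
    """
    mort_countries = set(surface.countries)
    lo, hi = required_span
    years_needed = set(range(lo, hi + 1))
    have_years = set(surface.years)
    if not years_needed <= have_years:
        raise ValidationError(
            f"mortality surface must span {lo}-{hi}; missing years {sorted(years_needed - have_years)}"
        )

    reasons: dict[str, str] = {}
    gni_by_country = gni.frame.groupby("country")["year"].apply(set).to_dict()
    pop_countries = set(population.countries)

    universe = sorted(mort_countries | set(gni_by_country) | pop_countries)
    included = []
    for c in universe:
        if c not in mort_countries:
            reasons[c] = "no mortality rate estimates"
        elif c not in gni_by_country:
            reasons[c] = "no GNI data"
        elif anchor_year not in gni_by_country[c]:
            reasons[c] = f"no GNI observation for anchor year {anchor_year}"
        elif len([y for y in gni_by_country[c] if y <= anchor_year]) < 2:
            reasons[c] = "fewer than 2 GNI observations for growth fitting"
        elif c not in pop_countries:
            reasons[c] = "no population data"
        else:
            included.append(c)
    if not included:
        raise ValidationError("empty panel: every country is missing at least one input")
    excluded = tuple(sorted(reasons))
    return PanelValidation(tuple(included), excluded, reasons)
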