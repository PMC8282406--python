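"""Model/Results interface over the full valuation pipeline.

:class:`IemvModel` bundles the three input tables with the valuation and
demographic conventions; :meth:`IemvModel.fit` runs the pipeline — panel
validation and exclusion, income classification, GNI growth fitting and
projection, scenario trajectory construction, life tables, VSMU schedules,
SMU risk differences, and IEMV cells — and returns an :class:`IemvResults`
carrying every intermediate surface, long-format accessors, group
aggregation, a text ``summary()``, and a diagnostic plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demography, iemv_aggregate, trajectories, valuation
from .core_model import (
    AGE_STARTS,
    CAUSES,
    HIGH_INCOME,
    N_AGE_GROUPS,
    SEXES,
    GniSeries,
    MortalitySurface,
    PanelValidation,
    PopulationTable,
    classify_income_group,
    read_gni_table,
    read_mortality_table,
    read_population_table,
    validate_panel,
)
from .trajectories import COUNTERFACTUAL_SCENARIOS, TrajectorySet
from .valuation import GniProjection, ValuationParams

__all__ = ["IemvModel", "IemvResults"]

_REFERENCE_AGE_INDEX = valuation.REFERENCE_AGE_START // 5


class IemvModel:
    """Income-equivalent monetary valuation of cause-specific mortality change.

    Parameters
    ----------
    mortality, gni, population
        The three validated input tables. Countries whose 2016 GNI classifies
        above the UMIC band are used only as the UMIC trajectory reference
        group and receive no valuation of their own.
    params
        Valuation scenario parameters; defaults to the primary scenario
        (unit elasticity, income ratio capped at 1).
    prob_convention
        Rate-to-probability conversion: ``"constant_hazard"`` (default) or
        ``"midpoint"``.
    classification_year
        GNI year used for income-group classification (2016 World Bank bands).
    """

    def __init__(
        self,
        mortality: MortalitySurface,
        gni: GniSeries,
        population: PopulationTable,
        params: ValuationParams | None = None,
        *,
        reference_year: int = 2016,
        horizon: int = 2030,
        classification_year: int = 2016,
        gni_anchor_year: int = 2017,
        growth_window: tuple[int, int] = valuation.GROWTH_WINDOW,
        prob_convention: str = "constant_hazard",
        zero_floor: float = trajectories.ZERO_FLOOR,
        reference_surface: MortalitySurface | None = None,
    ) -> None:
        self.mortality = mortality
        self.gni = gni
        self.population = population
        self.params = params if params is not None else ValuationParams()
        self.reference_year = reference_year
        self.horizon = horizon
        self.classification_year = classification_year
        self.gni_anchor_year = gni_anchor_year
        self.growth_window = growth_window
        if prob_convention not in demography.CONVENTIONS:
            raise ValueError(f"prob_convention must be one of {demography.CONVENTIONS}")
        self.prob_convention = prob_convention
        self.zero_floor = zero_floor
        self.reference_surface = reference_surface

    @classmethod
    def from_csv(cls, mortality_path, gni_path, population_path, params=None, **kwargs):
        """Build the model from the three canonical CSV files."""
        return cls(
            read_mortality_table(mortality_path),
            read_gni_table(gni_path),
            read_population_table(population_path),
            params,
            **kwargs,
        )

    @classmethod
    def from_frames(cls, mortality_df, gni_df, population_df, params=None, **kwargs):
        return cls(
            MortalitySurface.from_frame(mortality_df),
            GniSeries.from_frame(gni_df),
            PopulationTable.from_frame(population_df),
            params,
            **kwargs,
        )

    # ------------------------------------------------------------------
    def classify_countries(self) -> dict[str, str]:
        """Income group of every country with a classification-year GNI value."""
        frame = self.gni.frame
        sub = frame[frame["year"] == self.classification_year]
        return {
            row.country: classify_income_group(row.gni_pc)
            for row in sub.itertuples()
        }

    def fit(self) -> "IemvResults":
        validation = validate_panel(
            self.mortality,
            self.gni,
            self.population,
            required_span=(self.reference_year, self.horizon),
            anchor_year=self.gni_anchor_year,
        )
        income_map_all = self.classify_countries()
        included = [c for c in validation.included if c in income_map_all]
        income_map = {c: income_map_all[c] for c in included}
        analysis = [c for c in included if income_map[c] != HIGH_INCOME]
        if not analysis:
            raise ValueError("no LIC/LMIC/UMIC countries remain after validation")

        surface = self.mortality.restrict(included)
        traj = trajectories.build_trajectories(
            surface,
            income_map,
            reference_year=self.reference_year,
            horizon=self.horizon,
            zero_floor=self.zero_floor,
            reference_surface=self.reference_surface,
        )

        # Growth fitting and GNI projection for the analysis groups.
        analysis_map = {c: income_map[c] for c in analysis}
        gni_analysis = self.gni.restrict(analysis)
        group_growth = valuation.group_mean_growth(gni_analysis, analysis_map, self.growth_window)
        projection = valuation.project_gni(
            gni_analysis,
            group_growth,
            analysis_map,
            anchor_year=self.gni_anchor_year,
            years=tuple(range(self.gni_anchor_year + 1, self.horizon + 1)),
        )

        value_years = list(range(self.gni_anchor_year, self.horizon + 1))
        gni_arr = projection.array(list(traj.countries), value_years)  # [c, y]
        vsl = valuation.vsl_for(gni_arr, self.params)  # [c, y]

        # Base-case life tables per country-sex-year over the valuation years.
        year_idx = [traj.years.index(y) for y in value_years]
        base_total = traj.rates[:, :, :, 0].sum(axis=2)[:, :, year_idx, :]  # [c, s, y, a]
        floored = np.maximum(base_total, self.zero_floor)
        lt = demography.build_life_table(floored, convention=self.prob_convention)
        e = lt.e  # [c, s, y, a]

        vsmu_ref = valuation.vsmu_reference(vsl, self.params)  # [c, y]
        e_ref = e[:, :, :, _REFERENCE_AGE_INDEX]  # [c, s, y]
        vsmu = valuation.vsmu_at_age(
            vsmu_ref[:, None, :, None], e, e_ref[:, :, :, None]
        )  # [c, s, y, a]

        # Conditional probabilities under every (cause_altered, scenario).
        totals = demography.total_mortality_all(traj)[:, :, :, :, year_idx, :]
        q_all = demography.rate_to_conditional_prob(
            totals, np.arange(N_AGE_GROUPS), convention=self.prob_convention
        )
        q_base = q_all[:, :, :, 0]  # identical across cause_altered by construction
        smu = demography.delta_smu(q_base[:, :, :, None], q_all)[:, :, :, 1:]  # [c,s,d,2,y,a]
        iemv = smu * vsmu[:, :, None, None, :, :]

        return IemvResults(
            model=self,
            validation=validation,
            income_map=income_map,
            trajectory_set=traj,
            group_growth=group_growth,
            projection=projection,
            value_years=tuple(value_years),
            vsl=vsl,
            life_table=lt,
            vsmu=vsmu,
            smu=smu,
            iemv=iemv,
        )


@dataclass
class IemvResults:
    """Fitted pipeline outputs.

    Dense arrays are indexed ``[country, sex, cause, scenario(high,low),
    year, age]`` for ``smu``/``iemv``, ``[country, sex, year, age]`` for
    ``vsmu`` and the life-table columns, and ``[country, year]`` for ``vsl``;
    ``value_years`` labels the year axis. Long-format accessors return tidy
    frames.
    """

    model: IemvModel
    validation: PanelValidation
    income_map: dict[str, str]
    trajectory_set: TrajectorySet
    group_growth: dict[str, float]
    projection: GniProjection
    value_years: tuple[int, ...]
    vsl: np.ndarray = field(repr=False)
    life_table: "demography.LifeTable" = field(repr=False)
    vsmu: np.ndarray = field(repr=False)
    smu: np.ndarray = field(repr=False)
    iemv: np.ndarray = field(repr=False)

    # -- label helpers --------------------------------------------------
    @property
    def countries(self) -> tuple[str, ...]:
        return self.trajectory_set.countries

    @property
    def excluded(self) -> tuple[str, ...]:
        return self.validation.excluded

    def _cell_index(self) -> pd.DataFrame:
        c, s, y, a = np.meshgrid(
            np.arange(len(self.countries)),
            np.arange(len(SEXES)),
            np.arange(len(self.value_years)),
            np.arange(N_AGE_GROUPS),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "country": np.array(self.countries)[c.ravel()],
                "sex": np.array(SEXES)[s.ravel()],
                "year": np.array(self.value_years)[y.ravel()],
                "age_start": AGE_STARTS[a.ravel()],
            }
        )

    # -- tidy accessors -------------------------------------------------
    def vsl_frame(self) -> pd.DataFrame:
        c, y = np.meshgrid(np.arange(len(self.countries)), np.arange(len(self.value_years)),
                           indexing="ij")
        return pd.DataFrame(
            {
                "country": np.array(self.countries)[c.ravel()],
                "year": np.array(self.value_years)[y.ravel()],
                "vsl": self.vsl.ravel(),
            }
        )

    def life_expectancy_frame(self) -> pd.DataFrame:
        df = self._cell_index()
        df["e"] = self.life_table.e.ravel()
        return df

    def vsmu_frame(self) -> pd.DataFrame:
        df = self._cell_index()
        df["vsmu"] = self.vsmu.ravel()
        return df

    def _scenario_index(self) -> pd.DataFrame:
        c, s, d, k, y, a = np.meshgrid(
            np.arange(len(self.countries)),
            np.arange(len(SEXES)),
            np.arange(len(CAUSES)),
            np.arange(len(COUNTERFACTUAL_SCENARIOS)),
            np.arange(len(self.value_years)),
            np.arange(N_AGE_GROUPS),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "country": np.array(self.countries)[c.ravel()],
                "sex": np.array(SEXES)[s.ravel()],
                "cause": np.array(CAUSES)[d.ravel()],
                "scenario": np.array(COUNTERFACTUAL_SCENARIOS)[k.ravel()],
                "year": np.array(self.value_years)[y.ravel()],
                "age_start": AGE_STARTS[a.ravel()],
            }
        )

    def smu_frame(self) -> pd.DataFrame:
        df = self._scenario_index()
        df["delta_smu"] = self.smu.ravel()
        return df

    def iemv_frame(self) -> pd.DataFrame:
        df = self._scenario_index()
        df["delta_smu"] = self.smu.ravel()
        df["iemv"] = self.iemv.ravel()
        return df

    def trajectory_frame(self) -> pd.DataFrame:
        return self.trajectory_set.to_frame()

    # -- aggregation ----------------------------------------------------
    def aggregate(self, year: int, *, weighted_ur: bool = True,
                  scale: str = "per_person") -> pd.DataFrame:
        """Income-group, population-weighted IEMV summary for one reporting year."""
        cells = self.iemv_frame()
        analysis_pop = self.model.population.restrict(list(self.countries))
        return iemv_aggregate.aggregate_group(
            cells,
            analysis_pop,
            self.income_map,
            year,
            value_col="iemv",
            weighted_ur=weighted_ur,
            scale=scale,
        )

    def aggregate_vsmu(self, year: int, *, weighted_ur: bool = True) -> pd.DataFrame:
        """Population-weighted group mean VSMU (with UR) for one reporting year."""
        analysis_pop = self.model.population.restrict(list(self.countries))
        return iemv_aggregate.aggregate_group(
            self.vsmu_frame(),
            analysis_pop,
            self.income_map,
            year,
            value_col="vsmu",
            weighted_ur=weighted_ur,
        )

    # -- reporting ------------------------------------------------------
    def group_mean_vsl(self) -> pd.Series:
        """Mean VSL per income group over all countries and valuation years."""
        df = self.vsl_frame()
        df["income_group"] = df["country"].map(self.income_map)
        return df.groupby("income_group")["vsl"].mean()

    def summary(self) -> str:
        p = self.model.params
        lines = []
        lines.append("Income-Equivalent Monetary Valuation of Mortality Risk Change")
        lines.append("=" * 62)
        lines.append(f"Valuation years: {self.value_years[0]}-{self.value_years[-1]}   "
                     f"(anchor {self.model.reference_year}, horizon {self.model.horizon})")
        lines.append(f"Rate->probability convention: {self.model.prob_convention}")
        lines.append(
            f"VSL transfer: base ${p.vsl_base:,.0f} at income ${p.i_base:,.0f}, "
            f"elasticity {p.epsilon:g}, "
            + (f"fixed income ratio 1/{p.fixed_ratio:g}" if p.fixed_ratio
               else f"ratio ceiling {p.ratio_ceiling:g}")
        )
        lines.append("")
        groups = sorted({g for g in self.income_map.values() if g != HIGH_INCOME})
        counts = {g: sum(1 for c in self.countries if self.income_map[c] == g) for g in groups}
        mean_vsl = self.group_mean_vsl()
        rows = []
        for g in groups:
            rows.append(
                {
                    "income_group": g,
                    "n_countries": counts[g],
                    "mean_growth_per_yr": self.group_growth.get(g, np.nan),
                    "mean_vsl_usd": mean_vsl.get(g, np.nan),
                }
            )
        table = pd.DataFrame(rows)
        lines.append(table.to_string(index=False,
                                     float_format=lambda v: f"{v:,.4f}" if abs(v) < 1 else f"{v:,.0f}"))
        n_ref = sum(1 for g in self.income_map.values() if g == HIGH_INCOME)
        lines.append("")
        lines.append(f"High-income reference countries (not valued): {n_ref}")
        if self.excluded:
            lines.append(f"Excluded countries: {len(self.excluded)}")
            for c in self.excluded:
                lines.append(f"  {c}: {self.validation.reasons[c]}")
        else:
            lines.append("Excluded countries: none")
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_iemv(self, income_group: str, sex: str = "F", year: int = 2030, ax=None):
        """Diagnostic panel: aggregate IEMV age profile per cause and scenario."""
        import matplotlib.pyplot as plt

        agg = self.aggregate(year)
        sub = agg[(agg["income_group"] == income_group) & (agg["sex"] == sex)]
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 5))
        for (cause, scenario), g in sub.groupby(["cause", "scenario"]):
            style = "-" if scenario == "high" else "--"
            ax.plot(g["age_start"], g["mean"], style, label=f"{cause} ({scenario})", lw=1)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("age group start (years)")
        ax.set_ylabel("IEMV, 2015 USD per person at risk")
        ax.set_title(f"{income_group} {sex} {year}: solid=high-performance, dashed=low-performance")
        ax.legend(fontsize=6, ncol=2)
        return ax
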