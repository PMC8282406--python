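"""Income-equivalent monetary values and population-weighted group summaries.

The IEMV of a cell is the product of its risk change (in SMUs) and the
matching VSMU, in 2015 USD per person at risk: positive when the scenario risk
is below the base-case, negative above, zero when equal. Group summaries are
population-weighted means over countries within an income group, reported for
the three years with age-specific population projections (2020, 2025, 2030),
with 95% uncertainty ranges taken as weighted empirical 2.5th/97.5th
percentiles of the country-level values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import POPULATION_YEARS, PopulationTable

__all__ = [
    "compute_iemv",
    "aggregate_group",
    "weighted_quantile",
    "AGGREGATE_YEARS",
]

AGGREGATE_YEARS = POPULATION_YEARS

_CELL_KEYS = ["country", "sex", "year", "age_start"]


def compute_iemv(smu: pd.DataFrame, vsmu: pd.DataFrame) -> pd.DataFrame:
    """Elementwise product of SMU deltas and VSMU values on matching strata.

    ``smu`` carries columns country, sex, year, age_start, cause, scenario,
    delta_smu; ``vsmu`` carries country, sex, year, age_start, vsmu. Every SMU
    stratum must find its VSMU, otherwise the missing strata are reported.
    """
    for col in _CELL_KEYS + ["cause", "scenario", "delta_smu"]:
        if col not in smu.columns:
            raise ValueError(f"SMU table missing column {col!r}")
    for col in _CELL_KEYS + ["vsmu"]:
        if col not in vsmu.columns:
            raise ValueError(f"VSMU table missing column {col!r}")
    merged = smu.merge(vsmu[_CELL_KEYS + ["vsmu"]], on=_CELL_KEYS, how="left", validate="m:1")
    missing = merged[merged["vsmu"].isna()]
    if len(missing):
        strata = missing[_CELL_KEYS].drop_duplicates().head(10)
        raise ValueError(
            "grid mismatch: no VSMU for strata:\n" + strata.to_string(index=False)
        )
    merged["iemv"] = merged["delta_smu"] * merged["vsmu"]
    return merged.drop(columns=["vsmu"])


def weighted_quantile(values, weights, q):
    """Weighted empirical quantile with plotting-position interpolation.

    Values are sorted; each carries cumulative-weight plotting position
    (cum_i - w_i/2) / W; the quantile interpolates linearly between adjacent
    positions and clamps to the extremes. A single value is returned for every
    q (degenerate distribution). Invariant to uniform rescaling of weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive total")
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    positions = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(q, positions, v)


def aggregate_group(
    cells: pd.DataFrame,
    population: PopulationTable,
    income_map: dict[str, str],
    year: int,
    *,
    value_col: str = "iemv",
    weighted_ur: bool = True,
    scale: str = "per_person",
) -> pd.DataFrame:
    """Population-weighted income-group summary of per-country cell values.

    For each (income_group, sex, age, cause, scenario) stratum the mean is
    sum_c w_c x_c / sum_c w_c with w_c the country's population in that
    sex-age stratum, and the 95% UR the weighted (or unweighted, with
    ``weighted_ur=False``) empirical 2.5/97.5 percentiles of the country
    values. ``scale="total"`` additionally reports the population-scaled total
    (mean x group population). Only the three reporting years are accepted.
    """
    if year not in AGGREGATE_YEARS:
        raise ValueError(
            f"aggregation is restricted to years {AGGREGATE_YEARS} "
            f"(age-specific population projections exist only there); got {year}"
        )
    if scale not in ("per_person", "total"):
        raise ValueError("scale must be 'per_person' or 'total'")
    sub = cells[cells["year"] == year]
    if sub.empty:
        raise ValueError(f"no cells for year {year}")
    weights = population.weights(year).rename(columns={"count": "weight"})
    merged = sub.merge(weights, on=["country", "sex", "age_start"], how="left", validate="m:1")
    if merged["weight"].isna().any():
        bad = merged.loc[merged["weight"].isna(), "country"].unique()[:10]
        raise ValueError(f"population weights missing for countries {list(bad)} in {year}")
    merged["income_group"] = merged["country"].map(income_map)
    if merged["income_group"].isna().any():
        bad = merged.loc[merged["income_group"].isna(), "country"].unique()[:10]
        raise ValueError(f"no income group for countries {list(bad)}")

    group_cols = ["income_group", "sex", "age_start"]
    if "cause" in merged.columns:
        group_cols.append("cause")
    if "scenario" in merged.columns:
        group_cols.append("scenario")

    def _summarise(g: pd.DataFrame) -> pd.Series:
        x = g[value_col].to_numpy()
        w = g["weight"].to_numpy()
        total_w = w.sum()
        mean = float(np.dot(w, x) / total_w) if total_w > 0 else float(np.mean(x))
        if weighted_ur and total_w > 0:
            lo, hi = weighted_quantile(x, w, [0.025, 0.975])
        else:
            lo, hi = np.quantile(x, [0.025, 0.975], method="linear")
        out = {
            "mean": mean,
            "ur_low": float(lo),
            "ur_high": float(hi),
            "weight_basis": float(total_w),
            "n_countries": int(g["country"].nunique()),
        }
        if scale == "total":
            out["total"] = mean * total_w
        return pd.Series(out)

    result = (
        merged.groupby(group_cols, sort=True)
        .apply(_summarise, include_groups=False)
        .reset_index()
    )
    result["year"] = year
    result["n_countries"] = result["n_countries"].astype(int)
    return result
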