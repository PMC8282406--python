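import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iemv import (
    ValuationParams,
    fit_growth_rate,
    load_scenario,
    project_gni,
    vsl_for,
    vsmu_at_age,
    vsmu_reference,
)
from iemv.core_model import GniSeries
from iemv.valuation import group_mean_growth, scenario_names

from _oracles import leastsq_log_growth


def series(country, years, values):
    return pd.DataFrame({"country": country, "year": years, "gni_pc": values})


class TestGrowthFit:
    def test_flat_series_zero_growth(self):
        df = series("AAA", range(2010, 2018), [500.0] * 8)
        assert fit_growth_rate(df, "AAA") == 0.0

    def test_doubling_series_closed_form(self):
        values = [1000.0 * 2 ** ((y - 2010) / 7) for y in range(2010, 2018)]
        df = series("AAA", range(2010, 2018), values)
        assert fit_growth_rate(df, "AAA") == pytest.approx(math.log(2) / 7, rel=1e-12)

    def test_noisy_series_matches_endpoint_analytic_and_ls_oracle(self):
        rng = np.random.default_rng(42)
        r, sd = 0.03, 0.02
        years = np.arange(2010, 2018)
        for _ in range(20):
            eps = rng.normal(0, sd, size=len(years))
            values = 1000.0 * np.exp(r * (years - 2010) + eps)
            df = series("AAA", years, values)
            fitted = fit_growth_rate(df, "AAA")
            # analytic endpoint value
            assert fitted == pytest.approx(
                (math.log(values[-1]) - math.log(values[0])) / 7, rel=1e-12
            )
            # least-squares-on-logs oracle agrees within the noise-implied bound
            assert abs(fitted - leastsq_log_growth(years, values)) < 6 * sd / 7

    def test_fewer_than_two_observations_rejected(self):
        df = series("AAA", [2017], [1000.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_growth_rate(df, "AAA")

    def test_shorter_window_uses_available_endpoints(self):
        df = series("AAA", [2014, 2017], [1000.0, 1000.0 * math.e ** 0.09])
        assert fit_growth_rate(df, "AAA") == pytest.approx(0.03, rel=1e-12)


class TestProjection:
    def _gni(self):
        rows = []
        for country, anchor in (("AAA", 1000.0), ("BBB", 2000.0)):
            for y in range(2010, 2018):
                rows.append({"country": country, "year": y, "gni_pc": anchor})
        return GniSeries.from_frame(pd.DataFrame(rows))

    def test_zero_growth_projection_constant(self):
        proj = project_gni(self._gni(), {"LIC": 0.0}, {"AAA": "LIC", "BBB": "LIC"})
        assert set(proj.frame[proj.frame["country"] == "AAA"]["gni_pc"]) == {1000.0}

    def test_doubling_growth_reaches_double_at_2030(self):
        r = math.log(2) / 13
        proj = project_gni(self._gni(), {"LIC": r}, {"AAA": "LIC", "BBB": "LIC"})
        v2030 = proj.frame.query("country == 'AAA' and year == 2030")["gni_pc"].iloc[0]
        assert v2030 == pytest.approx(2000.0, rel=1e-12)

    def test_shared_growth_preserves_anchor_ratio(self):
        proj = project_gni(self._gni(), {"LIC": 0.04}, {"AAA": "LIC", "BBB": "LIC"})
        wide = proj.frame.pivot(index="year", columns="country", values="gni_pc")
        np.testing.assert_allclose(wide["BBB"] / wide["AAA"], 2.0, rtol=1e-12)

    def test_missing_anchor_is_exclusion_error(self):
        df = series("AAA", [2010, 2014], [1000.0, 1100.0])
        gni = GniSeries.from_frame(df)
        with pytest.raises(ValueError, match="anchor"):
            project_gni(gni, {"LIC": 0.02}, {"AAA": "LIC"})

    def test_group_mean_growth_is_unweighted_country_mean(self):
        rows = []
        for country, r in (("AAA", 0.02), ("BBB", 0.04)):
            for y in range(2010, 2018):
                rows.append({"country": country, "year": y,
                             "gni_pc": 1000.0 * math.exp(r * (y - 2010))})
        gni = GniSeries.from_frame(pd.DataFrame(rows))
        out = group_mean_growth(gni, {"AAA": "LIC", "BBB": "LIC"})
        assert out["LIC"] == pytest.approx(0.03, rel=1e-12)


class TestVsl:
    def test_base_income_returns_base_vsl(self):
        for eps in (0.5, 1.0, 1.5):
            p = ValuationParams(epsilon=eps)
            assert vsl_for(p.i_base, p) == pytest.approx(p.vsl_base, rel=1e-14)

    def test_fixed_ratio_100_linear_scaling(self):
        p = load_scenario("sensitivity_3")
        assert vsl_for(500.0, p) == pytest.approx(p.vsl_base / 100, rel=1e-14)

    def test_fixed_ratio_sensitivity_scenarios_ratio_is_1_6(self):
        p160 = load_scenario("sensitivity_2")
        p100 = load_scenario("sensitivity_3")
        assert p160.epsilon == 1.0 and p100.epsilon == 1.0
        assert vsl_for(700.0, p100) / vsl_for(700.0, p160) == pytest.approx(1.6, rel=1e-14)

    def test_elasticity_one_point_five_power_scaling(self):
        p = load_scenario("sensitivity_1")
        assert p.epsilon == 1.5
        gni = 0.04 * p.i_base
        assert vsl_for(gni, p) == pytest.approx(p.vsl_base * 0.04**1.5, rel=1e-12)
        assert vsl_for(gni, p) == pytest.approx(p.vsl_base * 0.008, rel=1e-12)

    def test_ceiling_caps_rich_countries_at_base(self):
        p = ValuationParams()
        assert vsl_for(2 * p.i_base, p) == pytest.approx(p.vsl_base, rel=1e-14)

    @given(st.floats(min_value=1.0, max_value=2e5), st.floats(min_value=1.01, max_value=3.0))
    @settings(max_examples=150, deadline=None)
    def test_monotone_nondecreasing_in_income(self, gni, step):
        p = ValuationParams(epsilon=1.2)
        assert vsl_for(gni * step, p) >= vsl_for(gni, p)

    def test_nonpositive_income_rejected(self):
        with pytest.raises(ValueError):
            vsl_for(0.0, ValuationParams())

    def test_scenario_table_complete(self):
        assert set(scenario_names()) == {"primary", "sensitivity_1", "sensitivity_2",
                                         "sensitivity_3"}

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ValuationParams(epsilon=0.0)
        with pytest.raises(ValueError):
            ValuationParams(smu_size=1e-3)
        with pytest.raises(ValueError):
            ValuationParams(reference_age_start=40)


class TestVsmu:
    def test_reference_vsmu_is_vsl_per_smu(self):
        p = ValuationParams()
        assert vsmu_reference(9_400_000.0, p) == pytest.approx(940.0, rel=1e-14)

    def test_linearity_in_vsl(self):
        p = ValuationParams()
        assert vsmu_reference(2.0e6, p) == pytest.approx(2 * vsmu_reference(1.0e6, p), rel=1e-14)

    def test_constant_ratio_across_countries(self):
        p = ValuationParams()
        vsls = np.array([1e5, 5e5, 2e6])
        np.testing.assert_allclose(vsmu_reference(vsls, p) / vsls, p.smu_size, rtol=1e-14)

    def test_age_scaling_identity_and_proportionality(self):
        assert vsmu_at_age(940.0, 30.0, 30.0) == pytest.approx(940.0, rel=1e-14)
        assert vsmu_at_age(940.0, 15.0, 30.0) == pytest.approx(470.0, rel=1e-14)

    def test_monotone_decreasing_e_gives_monotone_decreasing_vsmu(self):
        e = np.linspace(70, 2, 20)  # strictly decreasing life expectancy
        values = vsmu_at_age(940.0, e, e[7])
        assert np.all(np.diff(values) < 0)
        assert values[7] == pytest.approx(940.0, rel=1e-14)

    def test_nonpositive_reference_e_rejected(self):
        with pytest.raises(ValueError):
            vsmu_at_age(940.0, 10.0, 0.0)
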