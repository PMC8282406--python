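import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iemv import build_trajectories, log_linear_path, percentile_target
from iemv.core_model import CAUSES, SEXES, MortalitySurface
from iemv.trajectories import SCENARIOS, ZERO_FLOOR

from _oracles import quantile_sorted_interp


class TestPercentileTarget:
    def test_degenerate_distribution_returns_common_rate(self):
        refs = [0.004] * 6
        assert percentile_target(refs, "high") == pytest.approx(0.004)
        assert percentile_target(refs, "low") == pytest.approx(0.004)

    def test_high_target_below_low_target(self):
        refs = np.arange(1, 11) / 1000.0
        assert percentile_target(refs, "high") < percentile_target(refs, "low")

    @pytest.mark.parametrize("scenario,p", [("high", 0.10), ("low", 0.90)])
    def test_matches_independent_sort_and_interpolate_oracle(self, scenario, p):
        refs = np.array([2, 4, 6, 8, 10]) / 10_000.0
        assert percentile_target(refs, scenario) == pytest.approx(
            quantile_sorted_interp(refs, p), rel=1e-14
        )

    def test_fewer_than_two_references_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            percentile_target([0.01], "high")
        with pytest.raises(ValueError, match="reference"):
            percentile_target([], "low")

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=0.5), min_size=2, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_order_invariance_and_oracle_agreement(self, refs, rnd):
        shuffled = list(refs)
        rnd.shuffle(shuffled)
        for scenario, p in (("high", 0.10), ("low", 0.90)):
            a = percentile_target(refs, scenario)
            b = percentile_target(shuffled, scenario)
            assert a == b
            assert a == pytest.approx(quantile_sorted_interp(refs, p), rel=1e-12, abs=1e-300)


class TestLogLinearPath:
    def test_endpoint_identities(self):
        assert log_linear_path(0.02, 0.005, 2016) == 0.02
        assert log_linear_path(0.02, 0.005, 2030) == 0.005

    def test_midpoint_is_geometric_mean(self):
        assert log_linear_path(0.01, 0.0025, 2023) == pytest.approx(0.005, rel=1e-12)

    def test_year_outside_window_rejected(self):
        for year in (2015, 2031):
            with pytest.raises(ValueError, match="year"):
                log_linear_path(0.01, 0.005, year)

    def test_zero_rate_floored_not_fatal(self):
        value = log_linear_path(0.0, 0.01, 2023)
        assert value == pytest.approx(np.sqrt(ZERO_FLOOR * 0.01), rel=1e-9)

    @given(
        st.floats(min_value=1e-6, max_value=0.5),
        st.floats(min_value=1e-6, max_value=0.5),
        st.integers(min_value=2016, max_value=2030),
        st.floats(min_value=0.5, max_value=4.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_scale_equivariance(self, r0, r1, year, k):
        """Doubling (or any scaling of) both endpoints scales the whole path."""
        assert log_linear_path(k * r0, k * r1, year) == pytest.approx(
            k * log_linear_path(r0, r1, year), rel=1e-12
        )

    @given(
        st.floats(min_value=1e-6, max_value=0.5),
        st.floats(min_value=1e-6, max_value=0.5),
        st.floats(min_value=1e-6, max_value=0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_pathwise_ordering_follows_target_ordering(self, anchor, t1, t2):
        lo_t, hi_t = sorted((t1, t2))
        years = np.arange(2016, 2031)
        path_lo = log_linear_path(anchor, lo_t, years)
        path_hi = log_linear_path(anchor, hi_t, years)
        assert np.all(path_lo <= path_hi + 1e-300)


class TestBuildTrajectories:
    def test_base_path_is_input_forecast_unchanged(self, small_world):
        surface, gni, _, truth = small_world
        traj = build_trajectories(surface, truth["group_of"])
        arr, countries, years = surface.to_array()
        for country in traj.countries[:3]:
            ci = countries.index(country)
            y_pos = [years.index(y) for y in traj.years]
            np.testing.assert_array_equal(
                traj.rates[traj.countries.index(country), :, :, 0],
                arr[ci][:, :, y_pos, :],
            )

    def test_anchor_and_planted_target_exact(self, small_world):
        surface, _, _, truth = small_world
        traj = build_trajectories(surface, truth["group_of"])
        arr, countries, years = surface.to_array()
        labels = truth["rate_labels"]
        # independently recompute one LIC target from the planted LMIC 2030 rates
        lmic_idx = [labels["countries"].index(c) for c in truth["countries_by_group"]["LMIC"]]
        rates_2030 = truth["rates_2030"]
        i = traj.countries.index(truth["countries_by_group"]["LIC"][0])
        for si in range(2):
            for di in (0, 6):
                for ai in (0, 10, 19):
                    pool = rates_2030[lmic_idx, si, di, ai]
                    assert traj.targets[i, si, di, 0, ai] == pytest.approx(
                        quantile_sorted_interp(pool, 0.10), rel=1e-12
                    )
                    assert traj.targets[i, si, di, 1, ai] == pytest.approx(
                        quantile_sorted_interp(pool, 0.90), rel=1e-12
                    )
                    # path endpoints: 2016 anchor and 2030 target, exactly
                    ci = countries.index(traj.countries[i])
                    anchor = arr[ci, si, di, years.index(2016), ai]
                    assert traj.rates[i, si, di, 1, 0, ai] == anchor
                    assert traj.rates[i, si, di, 1, -1, ai] == traj.targets[i, si, di, 0, ai]

    def test_high_path_never_exceeds_low_path(self, small_world):
        surface, _, _, truth = small_world
        traj = build_trajectories(surface, truth["group_of"])
        assert np.all(traj.rates[:, :, :, 1] <= traj.rates[:, :, :, 2] * (1 + 1e-12))

    def test_reference_country_order_invariance(self, small_world):
        surface, _, _, truth = small_world
        shuffled = MortalitySurface.from_frame(
            surface.frame.rename(columns={"age_start": "age_group_start"})
            .sample(frac=1, random_state=7)
            .reset_index(drop=True)
        )
        a = build_trajectories(surface, truth["group_of"])
        b = build_trajectories(shuffled, truth["group_of"])
        assert a.countries == b.countries
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_missing_reference_group_error_lists_countries(self, small_world):
        surface, _, _, truth = small_world
        no_aux = {c: g for c, g in truth["group_of"].items() if g != "HIC"}
        restricted = surface.restrict(sorted(no_aux))
        with pytest.raises(ValueError, match="UMC"):
            build_trajectories(restricted, no_aux)

    def test_cardinality_single_lic_with_lmic_references(self, small_world):
        surface, _, _, truth = small_world
        lic = truth["countries_by_group"]["LIC"][0]
        lmics = truth["countries_by_group"]["LMIC"]
        traj = build_trajectories(
            surface.restrict([lic]),
            {c: truth["group_of"][c] for c in [lic] + lmics},
            reference_surface=surface.restrict(lmics),
        )
        assert traj.countries == (lic,)
        assert traj.rates.shape == (1, 2, 8, len(SCENARIOS), 15, 20)
        # 14 interpolated years beyond the anchor for each of the 2 scenario paths
        assert len(traj.years) - 1 == 14

    def test_scenarios_computed_independently_across_causes(self, small_world):
        """Perturbing one cause's reference rates leaves other causes' paths alone."""
        surface, _, _, truth = small_world
        base = build_trajectories(surface, truth["group_of"])
        df = surface.frame.rename(columns={"age_start": "age_group_start"}).copy()
        lmic = set(truth["countries_by_group"]["LMIC"])
        mask = df["country"].isin(lmic) & (df["cause"] == "injuries") & (df["year"] == 2030)
        df.loc[mask, "rate"] *= 0.5
        perturbed = build_trajectories(MortalitySurface.from_frame(df), truth["group_of"])
        d_inj = CAUSES.index("injuries")
        keep = [d for d in range(8) if d != d_inj]
        lic_idx = [base.countries.index(c) for c in truth["countries_by_group"]["LIC"]]
        np.testing.assert_array_equal(
            base.rates[lic_idx][:, :, keep], perturbed.rates[lic_idx][:, :, keep]
        )
        assert not np.array_equal(
            base.rates[lic_idx][:, :, d_inj, 1:], perturbed.rates[lic_idx][:, :, d_inj, 1:]
        )
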