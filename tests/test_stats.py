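import numpy as np
import pandas as pd
import pytest

from migvar import stats as st


def simulate_trait(rng, n_ind=40, n_yr=3, s_a=3.0, s_e=1.0, slope=0.001,
                   n_colonies=4):
    ind = np.repeat(np.arange(n_ind), n_yr)
    col = ind % n_colonies
    dist = rng.uniform(50, 4600, n_ind)[ind]
    val = (220 + slope * dist + rng.normal(0, s_a, n_ind)[ind]
           + rng.normal(0, s_e, len(ind)))
    return val, ind, col, dist


class TestBuildPairs:
    def _df(self, rows):
        return pd.DataFrame([
            {"individual_id": r[0], "colony_lon": r[1], "colony_lat": r[2],
             "winter_lon": r[3], "winter_lat": r[4],
             "seasons": ["2020–21"], "median_distance_km": 500.0}
            for r in rows])

    def test_same_colony_close_winters_one_pair(self):
        df = self._df([("a", 4.0, 52.0, -5.0, 40.0), ("b", 4.0, 52.0, -3.9, 40.0)])
        ps = st.build_pairs(df, seed=0)
        assert len(ps.pairs) == 1

    def test_winters_too_far_no_pair(self):
        df = self._df([("a", 4.0, 52.0, -5.0, 40.0), ("b", 4.0, 52.0, -1.0, 38.5)])
        with pytest.warns(UserWarning, match="no valid pairs"):
            ps = st.build_pairs(df, seed=0)
        assert len(ps.pairs) == 0

    def test_both_constraints_required(self):
        # colonies ~260 km apart, winters 10 km apart
        df = self._df([("a", 4.0, 52.0, -5.0, 40.0), ("b", 4.0, 54.35, -5.0, 40.09)])
        with pytest.warns(UserWarning):
            ps = st.build_pairs(df, seed=0)
        assert len(ps.pairs) == 0

    def test_season_selection_deterministic(self):
        df = self._df([("a", 4.0, 52.0, -5.0, 40.0), ("b", 4.0, 52.0, -4.9, 40.0)])
        df.at[0, "seasons"] = ["2018–19", "2019–20", "2020–21"]
        s1 = st.build_pairs(df, seed=7).pairs["season_a"].iloc[0]
        s2 = st.build_pairs(df, seed=7).pairs["season_a"].iloc[0]
        assert s1 == s2


class TestRandomizationTest:
    def test_identical_groups_p_near_one(self):
        v = [0.1, 0.2, 0.3, 0.4, 0.5]
        p, obs = st.randomization_test(v, list(v), n_perm=999, seed=0)
        assert obs == 0.0
        assert p >= 0.5

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        within = rng.normal(0.0, 1.0, 6)
        between = rng.normal(1.5, 1.0, 6)
        p_ex, obs_ex = st.randomization_test_exhaustive(within, between)
        p_mc, obs_mc = st.randomization_test(within, between, n_perm=100_000, seed=1)
        assert obs_mc == pytest.approx(obs_ex)
        # agreement within Monte-Carlo error (3 sigma)
        se = np.sqrt(p_ex * (1 - p_ex) / 100_000)
        assert abs(p_mc - p_ex) < 3 * se + 1e-4

    def test_add_one_floor_for_disjoint_extreme_groups(self):
        # the add-one estimator can never return 0; for disjoint extreme
        # groups p sits at (1 + #median-preserving shuffles) / (n_perm + 1),
        # within a few counts of the 1/(n_perm+1) floor
        rng = np.random.default_rng(21)
        within = list(rng.uniform(0.0, 0.1, 12))
        between = list(10.0 + rng.uniform(0.0, 0.1, 12))
        p, _ = st.randomization_test(within, between, n_perm=10_000, seed=3)
        assert 1.0 / 10_001 <= p <= 5.0 / 10_001

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            st.randomization_test([], [1.0])


class TestVarianceComponents:
    def test_r_matches_component_formula(self):
        rng = np.random.default_rng(7)
        res = st.fit_variance_components(*simulate_trait(rng), trait="dep")
        assert res.R == pytest.approx(res.s_a2 / (res.s_a2 + res.s_eps2))
        assert 0.0 <= res.R <= 1.0

    def test_zero_individual_signal_gives_low_r(self):
        rng = np.random.default_rng(8)
        val, ind, col, dist = simulate_trait(rng, s_a=0.0, s_e=2.0)
        res = st.fit_variance_components(val, ind, col, dist)
        assert res.R <= 0.1

    def test_distance_fixed_effect_recovered(self):
        rng = np.random.default_rng(9)
        val, ind, col, dist = simulate_trait(rng, n_ind=60, slope=0.01)
        res = st.fit_variance_components(val, ind, col, dist)
        assert res.fixed_effects["distance"] == pytest.approx(0.01, abs=0.003)

    def test_winter_arrival_convention_drops_distance(self):
        rng = np.random.default_rng(10)
        val, ind, col, dist = simulate_trait(rng)
        res = st.fit_variance_components(val, ind, col, dist,
                                         include_distance=False)
        assert "distance" not in res.fixed_effects

    def test_too_few_repeated_individuals_raise(self):
        with pytest.raises(ValueError, match=">= 2 individuals"):
            st.fit_variance_components([1, 2, 3], ["a", "a", "b"],
                                       ["c", "c", "c"], [1, 1, 1])


class TestIndividualRepeatability:
    def test_conditional_residuals_match_matrix_oracle(self):
        # tiny balanced design, single colony: hand-checkable BLUP algebra
        rng = np.random.default_rng(11)
        val, ind, col, dist = simulate_trait(rng, n_ind=6, n_yr=3, n_colonies=1)
        res = st.fit_variance_components(val, ind, col, dist)
        # independent dense-matrix computation of s_eps2 * V^-1 (y - X beta)
        data = res._data
        X = np.column_stack([np.ones(len(data)), data["distance"]])
        beta = np.array([res.fixed_effects["Intercept"],
                         res.fixed_effects["distance"]])
        r = data["value"].to_numpy() - X @ beta
        Z = pd.get_dummies(data["individual_id"]).to_numpy(float)
        V = (res.s_colony2 * np.ones((len(data), len(data)))
             + res.s_a2 * Z @ Z.T + res.s_eps2 * np.eye(len(data)))
        cond = res.s_eps2 * np.linalg.inv(V) @ r
        ri = res.per_individual
        for ind_id, grp in data.groupby("individual_id"):
            s_i2 = (cond[grp.index] ** 2).sum() / (len(grp) - 1)
            row = ri[ri.individual_id == ind_id].iloc[0]
            assert row.s_i2 == pytest.approx(s_i2, rel=1e-8)
            assert row.R_i == pytest.approx(res.s_a2 / (res.s_a2 + s_i2), rel=1e-8)

    def test_mean_ri_consistent_with_r(self):
        rng = np.random.default_rng(12)
        res = st.fit_variance_components(*simulate_trait(rng, n_ind=80))
        ri = res.per_individual
        assert ri["R_i"].between(0, 1).all()
        assert abs(ri["R_i"].mean() - res.R) < 0.15

    def test_switchers_excluded(self):
        rng = np.random.default_rng(13)
        res = st.fit_variance_components(*simulate_trait(rng, n_ind=10))
        ri = st.individual_repeatability(res, exclude={"0", "3"})
        assert set(ri.individual_id) == {str(i) for i in range(10)} - {"0", "3"}


class TestBootstrapCI:
    def test_deterministic_given_seed_and_contains_estimate(self):
        rng = np.random.default_rng(14)
        res = st.fit_variance_components(*simulate_trait(rng, n_ind=30, n_yr=2))
        ci1 = st.bootstrap_ci(res, n_boot=30, seed=5)
        ci2 = st.bootstrap_ci(res, n_boot=30, seed=5)
        assert ci1 == ci2
        assert ci1[0] <= res.R <= ci1[1]


class TestDistanceModel:
    def test_exact_linear_relationship(self):
        x = np.array([100.0, 500, 1000, 2000, 4000])
        y = 0.9 - 2e-5 * x
        m = st.distance_model(y, x)
        assert m.r_squared == pytest.approx(1.0)
        assert m.slope_per_km == pytest.approx(-2e-5)
        assert m.p_value < 1e-10

    def test_closed_form_on_five_hand_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 2.5, 3.5, 3.0, 5.0])
        m = st.distance_model(y, x)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert m.slope_per_km == pytest.approx(slope)
        assert m.intercept == pytest.approx(y.mean() - slope * x.mean())
        assert m.df == (1, 3)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(15)
        rejections = 0
        for _ in range(400):
            x = rng.uniform(0, 1, 20)
            y = rng.normal(0, 1, 20)
            rejections += st.distance_model(y, x).p_value < 0.05
        assert 0.02 <= rejections / 400 <= 0.09

    def test_f_and_lrt_agree_on_significance_ordering(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(0, 1, 30)
        m1 = st.distance_model(0.5 * x + rng.normal(0, 0.1, 30), x)
        m2 = st.distance_model(rng.normal(0, 0.1, 30), x)
        assert (m1.p_value < m2.p_value) == (m1.lrt_p < m2.lrt_p)

    def test_zero_distance_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            st.distance_model([1.0, 2, 3], [5.0, 5, 5])


class TestResidualVariation:
    def test_observed_equals_predicted_gives_zero(self):
        x = np.array([100.0, 1000, 2000, 3000])
        between = st.distance_model(0.8 - 1e-4 * x, x, response="overlap")
        corrected, _ = st.residual_variation(0.8 - 1e-4 * x, x, between)
        assert np.allclose(corrected, 0.0, atol=1e-12)

    def test_hand_value(self):
        between = st.DistanceModel("o", intercept=0.5, slope_per_km=0.0,
                                   f_stat=0, df=(1, 1), p_value=1, lrt_stat=0,
                                   lrt_p=1, r_squared=0)
        corrected, _ = st.residual_variation([0.6, 0.4, 0.35], [1.0, 2.0, 3.0], between)
        assert corrected[0] == pytest.approx(0.1)

    def test_shared_linear_law_gives_flat_corrected_slope(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(100, 4000, 60)
        law = lambda d: 0.9 - 5e-5 * d
        between = st.distance_model(law(x) + rng.normal(0, 0.01, 60), x,
                                    response="overlap")
        x2 = rng.uniform(100, 4000, 60)
        _, model = st.residual_variation(law(x2) + rng.normal(0, 0.01, 60),
                                         x2, between)
        assert abs(model.slope_per_km) < 5e-6
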