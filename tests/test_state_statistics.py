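"""Correlation analyses: Spearman, Bonferroni ranking, profiles, stability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from speechstate.state_statistics import (
    fisher_z_compare,
    half_split_stability,
    individual_profiles,
    population_feature_correlations,
    profile_similarity,
    spearman,
    williams_compare,
)


class TestSpearman:
    def test_hand_oracle(self):
        # d = (1-3, 2-1, 3-2) -> sum d^2 = 6; rho = 1 - 6*6/(3*8) = -0.5
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_monotone_identity(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_constant_series_missing(self):
        rho, p = spearman([1, 2, 3], [5, 5, 5])
        assert math.isnan(rho) and math.isnan(p)

    def test_missing_pairs_dropped(self):
        rho, _ = spearman([1, 2, np.nan, 3], [3, 1, 7, 2])
        assert rho == pytest.approx(-0.5)

    def test_too_few_pairs(self):
        assert math.isnan(spearman([1, 2], [2, 1])[0])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30) + 0.5 * x
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ties_average_ranks_match_scipy(self):
        x = [1, 1, 2, 3, 3, 3, 4]
        y = [2, 1, 2, 5, 4, 4, 9]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(min_value=-100, max_value=100), min_size=4, max_size=25))
def test_spearman_symmetry_and_monotone_invariance(x):
    rng = np.random.default_rng(7)
    y = list(rng.normal(size=len(x)))
    r_xy, _ = spearman(x, y)
    r_yx, _ = spearman(y, x)
    assert r_xy == pytest.approx(r_yx, nan_ok=True)
    # strictly monotone transform of x leaves rho unchanged
    x3 = [math.exp(v / 50.0) for v in x]
    r_t, _ = spearman(x3, y)
    assert r_t == pytest.approx(r_xy, nan_ok=True, abs=1e-9)


class TestPopulationCorrelations:
    def _table(self, n=40, n_features=6, seed=0):
        rng = np.random.default_rng(seed)
        ratings = rng.integers(1, 11, size=n).astype(float)
        data = {"participant_id": ["P"] * n, "provider_rating": ratings}
        data["f_equal"] = ratings
        for i in range(n_features - 1):
            data[f"f_noise{i}"] = rng.normal(size=n)
        return pd.DataFrame(data)

    def test_bonferroni_threshold_for_210_features(self):
        table = self._table()
        names = [c for c in table.columns if c.startswith("f_")]
        report = population_feature_correlations(table, feature_names=names)
        # alpha / n_features, as applied to the full 210-feature battery
        assert 0.05 / 210 == pytest.approx(2.381e-4, rel=1e-3)
        assert report.bonferroni_threshold == pytest.approx(0.05 / len(names))

    def test_feature_equal_to_rating_is_top_and_significant(self):
        report = population_feature_correlations(self._table())
        assert report.table.iloc[0]["feature"] == "f_equal"
        assert report.table.iloc[0]["rho"] == pytest.approx(1.0)
        assert bool(report.table.iloc[0]["significant"])

    def test_too_few_rated_calls_error(self):
        with pytest.raises(ValueError):
            population_feature_correlations(self._table(n=2))

    def test_bonferroni_subset_of_unadjusted(self):
        report = population_feature_correlations(self._table(n=60, seed=3))
        sig = report.table[report.table["significant"]]
        assert (sig["p"] < 0.05).all()


class TestIndividualProfiles:
    def _cohort_table(self, loadings, n_calls=40, seed=0, n_features=12):
        rng = np.random.default_rng(seed)
        frames = []
        for pid, load in loadings.items():
            state = rng.normal(5.5, 1.5, size=n_calls)
            data = {
                "participant_id": [pid] * n_calls,
                "provider_rating": np.round(np.clip(state, 1, 10)),
            }
            for i in range(n_features):
                data[f"f{i}"] = load[i] * state + rng.normal(0, 0.8, n_calls)
            frames.append(pd.DataFrame(data))
        return pd.concat(frames, ignore_index=True)

    def test_shared_loadings_high_similarity(self):
        load = np.array([1.0, -1.0] * 6)
        table = self._cohort_table({"A": load, "B": load, "C": load})
        profiles, sim = individual_profiles(table, min_calls=35)
        assert len(profiles) == 3
        assert sim > 0.8

    def test_independent_loadings_near_zero(self):
        rng = np.random.default_rng(11)
        loadings = {f"P{i}": rng.choice([-1, 1], size=12) for i in range(8)}
        table = self._cohort_table(loadings, seed=5)
        _, sim = individual_profiles(table, min_calls=35)
        assert abs(sim) < 0.15

    def test_single_qualifier_missing_similarity(self):
        load = np.ones(12)
        table = self._cohort_table({"A": load})
        profiles, sim = individual_profiles(table, min_calls=35)
        assert len(profiles) == 1 and math.isnan(sim)

    def test_min_call_threshold(self):
        load = np.ones(12)
        table = self._cohort_table({"A": load, "B": load}, n_calls=30)
        profiles, _ = individual_profiles(table, min_calls=35)
        assert profiles == []


class TestFisherZ:
    def test_closed_form_oracle(self):
        # z = (atanh(0.9) - 0) / sqrt(1/47 + 1/47)
        z, p = fisher_z_compare(0.9, 50, 0.0, 50)
        expected_z = math.atanh(0.9) / math.sqrt(2 / 47)
        assert z == pytest.approx(expected_z, abs=1e-12)
        assert p < 0.01

    def test_equal_correlations_p_one(self):
        _, p = fisher_z_compare(0.5, 40, 0.5, 40)
        assert p == pytest.approx(1.0)

    def test_small_samples_missing(self):
        z, p = fisher_z_compare(0.5, 3, 0.1, 50)
        assert math.isnan(z) and math.isnan(p)


class TestHalfSplitStability:
    def _participant_table(self, n=60, loading=1.0, seed=0, drift=0.0):
        rng = np.random.default_rng(seed)
        state = np.empty(n)
        state[0] = 5.5
        for t in range(1, n):  # AR(1), stationary sd ~1.4
            state[t] = 5.5 + 0.8 * (state[t - 1] - 5.5) + rng.normal(0, 0.85)
        state = np.clip(state, 1, 10)
        load = loading + drift * (np.arange(n) >= n // 2)
        data = {
            "participant_id": ["P"] * n,
            "call_time": pd.date_range("2024-01-01", periods=n, freq="D"),
            "provider_rating": np.round(np.clip(state + rng.normal(0, 0.3, n), 1, 10)),
        }
        for i in range(8):
            data[f"f{i}"] = load * state + rng.normal(0, 0.5, n)
        return pd.DataFrame(data)

    def test_duplicated_halves_fully_stable(self):
        half = self._participant_table(n=30)
        table = pd.concat([half, half], ignore_index=True)
        table["call_time"] = pd.date_range("2024-01-01", periods=60, freq="D")
        report = half_split_stability(table, min_half=10)
        assert (report.p_values.dropna() == 1.0).all()
        assert report.stable_fraction == 1.0

    def test_stationary_loadings_mostly_stable(self):
        # few features, all strongly loaded: allow one sampling rejection
        table = self._participant_table(n=80, seed=4)
        report = half_split_stability(table, min_half=10)
        assert report.stable_fraction >= 0.8

    def test_sign_flip_detected(self):
        table = self._participant_table(n=100, loading=1.0, drift=-2.0, seed=2)
        report = half_split_stability(table, min_half=10)
        assert report.stable_fraction < 0.5

    def test_too_few_calls_error(self):
        with pytest.raises(ValueError):
            half_split_stability(self._participant_table(n=15), min_half=10)

    def test_williams_variant_runs(self):
        table = self._participant_table(n=60, seed=9)
        report = half_split_stability(table, method="williams", min_half=10)
        assert 0.0 <= report.stable_fraction <= 1.0


def test_williams_compare_detects_difference():
    rng = np.random.default_rng(0)
    x = rng.normal(size=60)
    y_corr = x + rng.normal(0, 0.3, 60)
    x2 = rng.normal(size=60)
    y_uncorr = rng.normal(size=60)
    _, p = williams_compare(x, y_corr, x2, y_uncorr)
    assert p < 0.01


def test_profile_similarity_pairwise_missing_dropped():
    a = np.array([1.0, 0.5, np.nan, -0.5, 0.2])
    b = np.array([0.9, 0.4, 0.7, -0.6, np.nan])
    sim = profile_similarity(a, b)
    assert np.isfinite(sim) and sim > 0.9
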