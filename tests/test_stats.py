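import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netqual.stats import (StatsConfig, cognition_correlations,
                           covariate_contribution, dunn_sidak,
                           edgewise_comparison, gta_group_comparison,
                           permutation_test, residualize, t_test_from_summary)


def _tidy_profiles(values, subject_ids, metric="m", threshold=0.1):
    """Single-cell tidy profile table."""
    return pd.DataFrame({"subject_id": subject_ids, "threshold": threshold,
                         "metric": metric, "value": values})


def _cohort(n_a=10, n_b=10, seed=0, groups=("HS", "MS")):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    return pd.DataFrame({
        "subject_id": [f"s{i:02d}" for i in range(n)],
        "group": [groups[0]] * n_a + [groups[1]] * n_b,
        "age": rng.normal(44, 11, n),
        "education_years": rng.normal(14.5, 2.6, n),
    })


class TestDunnSidak:
    def test_identity_at_single_comparison(self):
        assert dunn_sidak(0.05, 1) == pytest.approx(0.05)

    def test_seven_comparisons_closed_form(self):
        assert dunn_sidak(0.05, 7) == pytest.approx(1 - 0.95 ** (1 / 7))
        assert round(dunn_sidak(0.05, 7), 5) == 0.0073

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(1e-4, 0.5), st.integers(1, 500))
    def test_bonferroni_sandwich(self, alpha, m):
        adj = dunn_sidak(alpha, m)
        assert alpha / m <= adj + 1e-15
        assert adj <= alpha + 1e-15

    def test_invalid_m(self):
        with pytest.raises(ValueError, match=">= 1"):
            dunn_sidak(0.05, 0)


class TestPermutationTest:
    def test_identical_multisets_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = permutation_test(a, a.copy(), n_perm=500, seed=1)
        assert res.observed_diff == 0.0
        assert res.p == 1.0

    def test_complete_separation_hits_floor(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(100, 0.1, 10)
        res = permutation_test(a, b, n_perm=1000, seed=2)
        assert res.p == pytest.approx(1.0 / 1001.0)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        r1 = permutation_test(a, b, n_perm=2000, seed=3)
        r2 = permutation_test(b, a, n_perm=2000, seed=3)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff)
        assert abs(r1.p - r2.p) < 0.03      # two-sided up to resampling noise

    def test_seed_reproducibility(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.3, 1, 10)
        assert permutation_test(a, b, 500, seed=9).p == \
            permutation_test(a, b, 500, seed=9).p

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            permutation_test([], [1.0], 100, 0)

    def test_type_one_error_calibrated(self):
        # scaled-down null calibration; the full one runs in acceptance
        rng = np.random.default_rng(7)
        rejections = sum(
            permutation_test(rng.normal(size=25), rng.normal(size=49),
                             n_perm=200, seed=i).p < 0.05
            for i in range(200))
        assert 0.02 <= rejections / 200 <= 0.09


class TestResidualize:
    def test_orthogonal_covariate_leaves_values(self):
        values = np.array([1.0, -1.0, 1.0, -1.0])
        cov = np.array([1.0, 1.0, -1.0, -1.0])
        assert np.allclose(residualize(values, cov), values)

    def test_perfect_fit_leaves_grand_mean(self, rng):
        age = rng.normal(0, 10, 30)      # centered predictor
        age -= age.mean()
        values = 3.0 * age + 7.0
        res = residualize(values, age)
        assert np.allclose(res, 7.0)

    def test_residuals_uncorrelated_with_covariates(self, rng):
        cov = rng.normal(size=(74, 2))
        values = 0.5 * cov[:, 0] - 1.2 * cov[:, 1] + rng.normal(size=74)
        res = residualize(values, cov)
        centered = res - res.mean()
        for j in range(2):
            c = cov[:, j] - cov[:, j].mean()
            assert abs(centered @ c) < 1e-8 * np.linalg.norm(centered) * \
                np.linalg.norm(c)

    def test_planted_slope_removed_across_seeds(self):
        # residual variance ~ noise variance once the age effect is removed
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            age = rng.normal(44, 11, 74)
            noise = rng.normal(0, 1, 74)
            values = 0.5 * age + noise
            res = residualize(values, age)
            ratios.append(res.var() / noise.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_collinear_columns_named(self):
        cov = pd.DataFrame({"age": np.arange(10.0),
                            "age2": 2.0 * np.arange(10.0)})
        with pytest.raises(ValueError, match="age"):
            residualize(np.random.default_rng(0).normal(size=10), cov)


class TestGtaGroupComparison:
    def test_planted_shift_detected_and_null_not(self, rng):
        cohort = _cohort(12, 12)
        ids = cohort["subject_id"]
        shifted = np.r_[rng.normal(0, 1, 12), rng.normal(2.5, 1, 12)]
        null = rng.normal(0, 1, 24)
        profiles = pd.concat([
            _tidy_profiles(shifted, ids, metric="shifted"),
            _tidy_profiles(null, ids, metric="null")])
        cfg = StatsConfig(n_perm=1000, seed=0)
        out = gta_group_comparison(profiles, cohort, [], cfg)
        p = out.set_index("metric")["p"]
        assert p["shifted"] < 0.01
        assert p["null"] > 0.05
        d = out.set_index("metric")["observed_diff"]
        assert d["shifted"] == pytest.approx(shifted[12:].mean()
                                             - shifted[:12].mean())

    def test_no_covariates_equals_plain_permutation(self, rng):
        # residualization with an empty model is the identity, so the
        # comparison reduces to a plain permutation test on the raw values
        values = rng.normal(0, 1, 17)
        assert np.array_equal(residualize(values, np.empty((17, 0))), values)
        cohort = _cohort(8, 9)
        profiles = _tidy_profiles(values, cohort["subject_id"])
        cfg = StatsConfig(n_perm=2000, seed=4)
        out = gta_group_comparison(profiles, cohort, [], cfg)
        direct = permutation_test(values[8:], values[:8], 2000, seed=4)
        assert out["observed_diff"].iloc[0] == pytest.approx(direct.observed_diff)
        assert abs(out["p"].iloc[0] - direct.p) < 0.05

    def test_covariate_explains_away_group_difference(self, rng):
        # group difference entirely mediated by a measured covariate
        cohort = _cohort(20, 20)
        quality = np.r_[rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        cohort["tsnr"] = quality
        values = 2.0 * quality + rng.normal(0, 0.3, 40)
        profiles = _tidy_profiles(values, cohort["subject_id"])
        cfg = StatsConfig(n_perm=1000, seed=5)
        raw = gta_group_comparison(profiles, cohort, [], cfg)
        adj = gta_group_comparison(profiles, cohort, ["tsnr"], cfg)
        assert raw["p"].iloc[0] < 0.01
        assert adj["p"].iloc[0] > 0.05


class TestCovariateContribution:
    def test_planted_dependence_hits_floor(self, rng):
        cohort = _cohort(15, 15)
        cohort["cnr"] = rng.normal(0, 1, 30)
        values = 5.0 * cohort["cnr"].to_numpy() + rng.normal(0, 0.5, 30)
        profiles = _tidy_profiles(values, cohort["subject_id"])
        cfg = StatsConfig(n_perm=500, seed=6)
        out = covariate_contribution(profiles, cohort, "cnr",
                                     ["age", "cnr"], cfg)
        assert out["p"].iloc[0] == pytest.approx(1 / 501)

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        n_runs = 300
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            cohort = _cohort(10, 10, seed=seed)
            cohort["cnr"] = rng.normal(size=20)
            values = rng.normal(size=20)
            profiles = _tidy_profiles(values, cohort["subject_id"])
            cfg = StatsConfig(n_perm=99, seed=seed)
            out = covariate_contribution(profiles, cohort, "cnr", ["cnr"], cfg)
            hits += out["p"].iloc[0] < 0.05
        assert 0.02 <= hits / n_runs <= 0.09

    def test_constant_covariate_rejected(self):
        cohort = _cohort(5, 5)
        cohort["cnr"] = 1.0
        profiles = _tidy_profiles(np.arange(10.0), cohort["subject_id"])
        with pytest.raises(ValueError, match="constant"):
            covariate_contribution(profiles, cohort, "cnr", ["cnr"],
                                   StatsConfig(n_perm=10, seed=0))


class TestCognitionCorrelations:
    def _setup(self, rng, n=40):
        cohort = _cohort(n // 2, n // 2, seed=1)
        for s in ("sdmt", "cvlt", "bvmt", "cowat", "fsmc", "bicams_scaled",
                  "bicams_z"):
            cohort[s] = rng.normal(size=n)
        return cohort

    def test_exact_copy_gives_unit_correlation(self, rng):
        cohort = self._setup(rng)
        values = cohort["sdmt"].to_numpy()
        profiles = _tidy_profiles(values, cohort["subject_id"])
        out = cognition_correlations(profiles, cohort,
                                     StatsConfig(seed=0, n_perm=10))
        row = out[(out["score"] == "sdmt")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_family_size_and_corrected_alpha(self, rng):
        cohort = self._setup(rng)
        profiles = pd.concat([
            _tidy_profiles(rng.normal(size=40), cohort["subject_id"],
                           metric=f"m{k}") for k in range(7)])
        out = cognition_correlations(profiles, cohort,
                                     StatsConfig(seed=0, n_perm=10))
        assert out.attrs["m_comparisons"] == 49
        assert out.attrs["alpha_corrected"] == pytest.approx(
            dunn_sidak(0.05, 49))
        # an uncorrected-significant p like 0.008 does not survive m=49
        assert dunn_sidak(0.05, 49) < 0.008
        assert not out.loc[(out["p"] > dunn_sidak(0.05, 49)),
                           "significant"].any()

    def test_familywise_error_controlled_under_global_null(self):
        families_with_hit = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            cohort = self._setup(rng)
            profiles = pd.concat([
                _tidy_profiles(rng.normal(size=40), cohort["subject_id"],
                               metric=f"m{k}") for k in range(7)])
            out = cognition_correlations(profiles, cohort,
                                         StatsConfig(seed=seed, n_perm=10))
            families_with_hit += out["significant"].any()
        # FWER <= alpha: expect <= ~10 of 200, allow 3 binomial sd
        assert families_with_hit <= 10 + 3 * np.sqrt(200 * 0.05 * 0.95)

    def test_constant_score_rejected(self, rng):
        cohort = self._setup(rng)
        cohort["cvlt"] = 5.0
        profiles = _tidy_profiles(rng.normal(size=40), cohort["subject_id"])
        with pytest.raises(ValueError, match="cvlt"):
            cognition_correlations(profiles, cohort, StatsConfig(n_perm=10))


class TestEdgewise:
    def _stack(self, rng, n_subj, n=6, shift=None):
        mats = []
        for s in range(n_subj):
            w = np.clip(rng.normal(0.3, 0.05, (n, n)), -0.9, 0.9)
            w = (w + w.T) / 2
            if shift is not None:
                w[0, 1] = w[1, 0] = w[0, 1] + shift
            np.fill_diagonal(w, 0)
            mats.append(w)
        return np.stack(mats)

    def test_identical_groups_have_small_effect_sizes(self, rng):
        stack = np.concatenate([self._stack(rng, 15), self._stack(rng, 15)])
        groups = np.array(["A"] * 15 + ["B"] * 15)
        res = edgewise_comparison(stack, groups, StatsConfig(n_perm=300, seed=0))
        assert np.abs(res.d).max() < 1.2
        assert abs(np.mean(res.d)) < 0.2

    def test_planted_edge_recovers_minimal_p(self, rng):
        a = self._stack(rng, 15)
        b = self._stack(rng, 15, shift=0.4)
        stack = np.concatenate([a, b])
        groups = np.array(["A"] * 15 + ["B"] * 15)
        res = edgewise_comparison(stack, groups,
                                  StatsConfig(n_perm=500, seed=1))
        iu = np.triu_indices(6, 1)
        assert res.p[0, 1] == res.p[iu].min() == pytest.approx(1 / 501)
        assert res.d[0, 1] > 0          # B minus A, B shifted up
        assert res.mean_fc["B"] > res.mean_fc["A"]

    def test_reduced_amplitude_group_has_lower_mean_fc(self, rng):
        a = self._stack(rng, 12)
        b = self._stack(rng, 12) * 0.7          # attenuated correlations
        stack = np.concatenate([a, b])
        groups = np.array(["HS"] * 12 + ["MS"] * 12)
        res = edgewise_comparison(stack, groups,
                                  StatsConfig(n_perm=300, seed=2))
        assert res.mean_fc["MS"] < res.mean_fc["HS"]
        assert np.median(res.d[np.triu_indices(6, 1)]) < 0


class TestTTestFromSummary:
    def test_identical_summaries(self):
        res = t_test_from_summary(10.0, 2.0, 20, 10.0, 2.0, 30)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.df == 48

    def test_printed_cohort_rows_reproduce(self):
        # verbal memory: 61.4 +/- 11.1 (n=49) vs 68.1 +/- 6.3 (n=25)
        cvlt = t_test_from_summary(61.4, 11.1, 49, 68.1, 6.3, 25)
        assert round(cvlt.p, 3) == 0.007
        # age: 44.7 +/- 11.1 (n=49) vs 41.6 +/- 12.7 (n=25)
        age = t_test_from_summary(44.7, 11.1, 49, 41.6, 12.7, 25)
        assert round(age.p, 2) == 0.28

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="at least 2"):
            t_test_from_summary(1, 1, 1, 2, 1, 5)
        with pytest.raises(ValueError, match="positive"):
            t_test_from_summary(1, 0, 5, 2, 1, 5)
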