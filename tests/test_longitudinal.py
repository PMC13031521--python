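"""Baseline normalization, trend statistics, BH, bootstrap and mixed model."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from gaitscore.errors import (
    InvalidArgumentError,
    MissingBaselineError,
    UndefinedStatisticError,
)
from gaitscore.longitudinal import (
    baseline_normalize,
    bh_adjust,
    bootstrap_ci,
    feature_time_trend,
    mixed_model_trend,
    normalize_trajectory,
    stage_stratified_top_features,
    top_mixed_model_features,
)
from gaitscore.simulate import simulate_feature_drift_cohort


def pearson_oracle(x, y):
    """From-definition covariance-formula Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (np.sqrt(np.mean((x - x.mean()) ** 2))
                  * np.sqrt(np.mean((y - y.mean()) ** 2)))


class TestBaselineNormalize:
    def test_relative_change(self):
        normed, unstable = normalize_trajectory([2.0, 3.0])
        assert normed[0] == 0.0
        assert normed[1] == pytest.approx(0.5)
        assert not unstable

    def test_constant_trajectory_all_zero(self):
        normed, _ = normalize_trajectory([7.0, 7.0, 7.0])
        assert np.all(normed == 0.0)

    def test_zero_baseline_guard_and_flag(self):
        normed, unstable = normalize_trajectory([0.0, 1.0])
        assert normed[1] == pytest.approx(1e8)
        assert unstable

    def test_difference_mode(self):
        normed, _ = normalize_trajectory([2.0, 3.5], mode="difference")
        assert normed[1] == pytest.approx(1.5)

    def test_missing_baseline_named(self):
        df = pd.DataFrame({"patient_id": ["p1", "p1"],
                           "visit_day": [100.0, 300.0], "f": [1.0, 2.0]})
        with pytest.raises(MissingBaselineError, match="p1"):
            baseline_normalize(df, ["f"])

    def test_dataframe_normalization(self):
        df = pd.DataFrame({
            "patient_id": ["a", "a", "b", "b"],
            "visit_day": [0.0, 200.0, 0.0, 250.0],
            "f": [2.0, 3.0, 4.0, 3.0],
        })
        out = baseline_normalize(df, ["f"])
        assert out.loc[out["visit_day"] == 0, "f"].tolist() == [0.0, 0.0]
        assert out.loc[(out["patient_id"] == "a") & (out["visit_day"] > 0),
                       "f"].iloc[0] == pytest.approx(0.5)
        assert out.loc[(out["patient_id"] == "b") & (out["visit_day"] > 0),
                       "f"].iloc[0] == pytest.approx(-0.25)


class TestTrend:
    def test_exact_linear_relation(self):
        days = np.array([0.0, 100, 200, 300, 400])
        tr = feature_time_trend(days, 0.001 * days)
        assert tr.r == pytest.approx(1.0)
        assert tr.r2 == pytest.approx(1.0)
        assert tr.p_raw < 1e-6

    def test_sign_antisymmetry(self, rng):
        days = rng.uniform(0, 500, size=30)
        vals = 0.01 * days + rng.normal(0, 0.5, size=30)
        a = feature_time_trend(days, vals)
        b = feature_time_trend(days, -vals)
        assert b.r == pytest.approx(-a.r, rel=1e-12)
        assert b.p_raw == pytest.approx(a.p_raw, rel=1e-9)

    def test_pearson_matches_covariance_oracle(self, rng):
        days = rng.uniform(0, 700, size=40)
        vals = rng.normal(size=40)
        tr = feature_time_trend(days, vals)
        assert tr.r == pytest.approx(pearson_oracle(days, vals), abs=1e-12)

    def test_null_type_one_error_rate(self, rng):
        """Independent values: the Wald p is uniform, so rejections at
        alpha = 0.05 occur in about 5% of replicates."""
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            days = rng.uniform(0, 600, size=20)
            vals = rng.normal(size=20)
            if feature_time_trend(days, vals).p_raw < 0.05:
                hits += 1
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            feature_time_trend([0, 100, 200], [1.0, 1.0, 1.0])


class TestBH:
    def test_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_equal_identity(self):
        assert np.allclose(bh_adjust([0.2] * 7), 0.2)

    def test_monotone_in_raw_order(self, rng):
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=15)
        adj = bh_adjust(p)
        perm = rng.permutation(15)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_matches_reference_implementation_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bh_adjust([0.5, 1.5])


class TestBootstrap:
    def _df(self, rng, n_patients=20, r_like=True):
        rows = []
        for i in range(n_patients):
            for day in (0.0, rng.uniform(180, 700)):
                val = (0.002 * day if r_like else rng.normal()) \
                    + rng.normal(0, 0.2)
                rows.append({"patient_id": f"p{i}", "visit_day": day,
                             "f": val})
        return pd.DataFrame(rows)

    def test_perfect_linear_collapses_to_one(self):
        rows = []
        for i in range(6):
            for day in (0.0, 300.0 + 10 * i):
                rows.append({"patient_id": f"p{i}", "visit_day": day,
                             "f": 0.01 * day})
        lo, hi = bootstrap_ci(pd.DataFrame(rows), "f", n_resamples=100, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_bounds_ordered_and_in_range(self, rng):
        lo, hi = bootstrap_ci(self._df(rng), "f", n_resamples=200, seed=1)
        assert -1 <= lo <= hi <= 1

    def test_deterministic_under_seed(self, rng):
        df = self._df(rng)
        assert bootstrap_ci(df, "f", n_resamples=100, seed=3) == \
            bootstrap_ci(df, "f", n_resamples=100, seed=3)

    def test_coverage_of_generating_correlation(self):
        """CI covers the true r in roughly 95% of replications."""
        master = np.random.default_rng(2024)
        covered = 0
        n_rep = 60
        true_r = 0.6
        for _ in range(n_rep):
            rows = []
            for i in range(30):
                for day in (0.0, float(master.uniform(100, 800))):
                    z = day / 800.0
                    val = true_r * z + np.sqrt(1 - true_r**2) \
                        * master.normal() * 0.29
                    rows.append({"patient_id": f"p{i}", "visit_day": day,
                                 "f": val})
            df = pd.DataFrame(rows)
            r_true = pearson_oracle(df["visit_day"], df["f"])
            lo, hi = bootstrap_ci(df, "f", n_resamples=200,
                                  seed=int(master.integers(2**31)))
            covered += lo <= r_true <= hi
        # patient-level bootstrap of a pooled statistic: accept 85-100%
        assert covered / n_rep >= 0.80


class TestStratified:
    def test_stratum_specific_drift_ranks_first(self, rng):
        rows = []
        for i in range(16):
            grade = i % 4
            for day in (0.0, float(rng.uniform(200, 700))):
                special = 0.003 * day if grade == 2 else 0.0
                rows.append({
                    "patient_id": f"p{i}", "visit_day": day,
                    "baseline_grade": grade,
                    "f_special": special + rng.normal(0, 0.05),
                    "f_noise": rng.normal(0, 1.0),
                })
        df = pd.DataFrame(rows)
        out = stage_stratified_top_features(df, ["f_special", "f_noise"])
        assert out["grade_2"].index[0] == "f_special"
        assert out["grade_2"].loc["f_special", "r"] > 0.9

    def test_insufficient_stratum_flagged(self, rng):
        df = pd.DataFrame({
            "patient_id": ["a", "a", "b", "b"],
            "visit_day": [0.0, 300.0, 0.0, 400.0],
            "baseline_grade": [0, 0, 0, 0],
            "f": rng.normal(size=4),
        })
        out = stage_stratified_top_features(df, ["f"])
        assert out["grade_3"] == "insufficient"

    def test_families_corrected_separately(self, rng):
        df = simulate_feature_drift_cohort(seed=1)
        feature_cols = [c for c in df.columns if c.startswith(("drift", "null"))]
        normed = baseline_normalize(df, feature_cols)
        out = stage_stratified_top_features(normed, feature_cols)
        overall = out["overall"]
        assert {"r", "p_raw", "p_bh", "spearman", "r2"} <= set(overall.columns)
        defined = overall["p_raw"].notna()
        assert np.allclose(
            overall.loc[defined, "p_bh"],
            bh_adjust(overall.loc[defined, "p_raw"]))


class TestMixedModel:
    def test_noise_free_slope_recovery(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            for v in range(3):
                f = rng.uniform(0, 2)
                rows.append({"patient_id": f"p{i}", "score": 2.0 * f,
                             "feat": f})
        table = mixed_model_trend(pd.DataFrame(rows), ["feat"])
        assert table.loc["feat", "slope"] == pytest.approx(2.0, abs=1e-4)
        assert table.loc["feat", "p_raw"] < 1e-6

    def test_patient_offsets_absorbed_by_random_intercept(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(12):
            offset = rng.normal(0, 1.0)
            for v in range(3):
                f = rng.uniform(0, 2)
                rows.append({"patient_id": f"p{i}",
                             "score": 1.5 * f + offset, "feat": f})
        table = mixed_model_trend(pd.DataFrame(rows), ["feat"])
        assert table.loc["feat", "slope"] == pytest.approx(1.5, abs=0.15)

    def test_top_features_ranked_by_adjusted_p(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(10):
            for v in range(3):
                f = rng.uniform(0, 2)
                rows.append({"patient_id": f"p{i}", "score": f +
                             rng.normal(0, 0.1),
                             "good": f, "noise1": rng.normal(),
                             "noise2": rng.normal()})
        table = mixed_model_trend(pd.DataFrame(rows),
                                  ["good", "noise1", "noise2"])
        top = top_mixed_model_features(table, k=1)
        assert top.index[0] == "good"
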