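"""Metric oracles, neighbor-class tests, attributions and fairness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gaitscore.errors import EmptyInputError, UndefinedStatisticError
from gaitscore.evaluation import (
    aggregate_attributions,
    classification_metrics,
    confounder_association,
    fairness_report,
    mann_whitney_u,
    neighbor_separation,
    regression_metrics,
)


def macro_f1_from_confusion(y_true, y_pred):
    """From-definition oracle: per-class F1 from the confusion counts."""
    labels = sorted(set(y_true) | set(y_pred), key=str)
    f1s = []
    for lab in labels:
        tp = sum(t == lab and p == lab for t, p in zip(y_true, y_pred))
        fp = sum(t != lab and p == lab for t, p in zip(y_true, y_pred))
        fn = sum(t == lab and p != lab for t, p in zip(y_true, y_pred))
        f1s.append(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s))


def kappa_from_definition(y_true, y_pred):
    labels = sorted(set(y_true) | set(y_pred), key=str)
    n = len(y_true)
    po = np.mean([t == p for t, p in zip(y_true, y_pred)])
    pe = sum((sum(t == lab for t in y_true) / n)
             * (sum(p == lab for p in y_pred) / n) for lab in labels)
    return (po - pe) / (1 - pe)


def exact_mwu_pvalue(x, y):
    """Full-enumeration two-sided p for the Mann-Whitney U (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = float(np.sum(np.asarray(x)[:, None] < np.asarray(y)[None, :]))
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(float(np.sum(xs[:, None] < ys[None, :])))
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        rep = regression_metrics([0, 1, 2, 3], [0, 1, 2, 3])
        assert rep.rmse == 0.0 and rep.r2 == 1.0

    def test_hand_example(self):
        rep = regression_metrics([0, 2], [1, 1])
        assert rep.rmse == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(0.0)

    def test_mean_predictor_r2_zero(self, rng):
        y = rng.normal(size=30)
        rep = regression_metrics(y, np.full(30, y.mean()))
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_per_score_rmse_consistency(self, rng):
        y = np.repeat([0.0, 1.0, 2.0], 10)
        pred = y + rng.normal(0, 0.3, size=30)
        rep = regression_metrics(y, pred)
        for level, value in rep.per_score_rmse.items():
            m = y == level
            assert value == pytest.approx(
                np.sqrt(np.mean((y[m] - pred[m]) ** 2)))

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            regression_metrics([2, 2, 2], [1, 2, 3])

    def test_matches_from_definition_oracle(self, rng):
        y = rng.normal(size=50)
        p = y + rng.normal(0, 0.5, size=50)
        rep = regression_metrics(y, p)
        assert rep.rmse == pytest.approx(
            np.sqrt(np.mean((y - p) ** 2)), rel=1e-12)
        assert rep.r2 == pytest.approx(
            1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), rel=1e-12)


class TestClassificationMetrics:
    def test_perfect_three_class(self):
        y = ["a", "b", "c"] * 4
        rep = classification_metrics(y, y)
        assert rep.macro_f1 == 1.0 and rep.kappa == 1.0

    def test_hand_confusion_example(self):
        rep = classification_metrics([0, 0, 1, 1], [0, 1, 1, 1])
        assert rep.macro_f1 == pytest.approx((2 / 3 + 4 / 5) / 2)

    def test_macro_f1_is_mean_of_per_class(self, rng):
        y = rng.integers(0, 4, size=60)
        p = rng.integers(0, 4, size=60)
        rep = classification_metrics(y, p)
        assert rep.macro_f1 == pytest.approx(np.mean(list(
            rep.per_class_f1.values())), rel=1e-12)
        assert rep.macro_f1 == pytest.approx(
            macro_f1_from_confusion(list(y), list(p)), rel=1e-12)

    def test_kappa_matches_definition(self, rng):
        y = list(rng.integers(0, 3, size=80))
        p = list(rng.integers(0, 3, size=80))
        rep = classification_metrics(y, p)
        assert rep.kappa == pytest.approx(kappa_from_definition(y, p),
                                          rel=1e-12)

    def test_random_permutation_kappa_near_zero(self, rng):
        y = np.repeat([0, 1, 2], 40)
        kappas = [classification_metrics(y, rng.permutation(y)).kappa
                  for _ in range(100)]
        assert abs(np.mean(kappas)) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            classification_metrics([], [])


class TestMannWhitney:
    def test_pinned_convention_and_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 9.0  # all 9 (x, y) pairs have x < y
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_groups_no_separation(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.5

    def test_u_complement_identity(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            u_xy, _ = mann_whitney_u(x, y)
            u_yx, _ = mann_whitney_u(y, x)
            assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6), (8, 7)])
    def test_exact_matches_enumeration(self, n1, n2, rng):
        x = rng.normal(0, 1, size=n1)
        y = rng.normal(0.8, 1, size=n2)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(exact_mwu_pvalue(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        """At n1 = n2 = 10 the tie-corrected normal approximation stays
        within 0.02 of the exact tail on shifted samples."""
        for _ in range(5):
            x = rng.normal(0, 1, size=10)
            y = rng.normal(0.7, 1, size=10)
            _, p_asym = mann_whitney_u(x, y, exact_max_n=0)  # force normal
            _, p_exact = mann_whitney_u(x, y, exact_max_n=10)
            assert abs(p_asym - p_exact) <= 0.02

    def test_neighbor_separation_ordering(self, rng):
        groups = {k: rng.normal(k, 0.2, size=12) for k in range(4)}
        tests = neighbor_separation(groups)
        assert [t.pair for t in tests] == [(0, 1), (1, 2), (2, 3)]
        assert all(t.p_value < 0.01 for t in tests)


class TestAttributions:
    def _provenance(self):
        rows = []
        for ch, cat in [("c1", "X-pos"), ("c2", "Dist")]:
            for d in ("mean", "var", "max"):
                rows.append((f"{ch}__{d}", ch, cat, d))
        return pd.DataFrame([r[1:] for r in rows], index=[r[0] for r in rows],
                            columns=["channel", "category", "descriptor"])

    def test_single_channel_dominance(self):
        prov = self._provenance()
        attr = pd.DataFrame(np.zeros((4, 6)), columns=prov.index)
        attr.loc[:, "c1__mean"] = 2.0
        imp = aggregate_attributions(attr, prov)
        assert imp.ranking[0] == "c1"
        assert imp.table.loc["c2", "importance"] == 0.0

    def test_conservation_identity(self, rng):
        prov = self._provenance()
        attr = pd.DataFrame(rng.normal(size=(10, 6)), columns=prov.index)
        imp = aggregate_attributions(attr, prov)
        total_by_channel = imp.table["importance"].sum()
        total_by_feature = attr.abs().mean(axis=0).sum()
        assert total_by_channel == pytest.approx(total_by_feature, rel=1e-9)

    def test_uniform_attributions_proportional_to_counts(self):
        prov = self._provenance()
        attr = pd.DataFrame(np.ones((5, 6)), columns=prov.index)
        imp = aggregate_attributions(attr, prov)
        assert imp.table.loc["c1", "importance"] == pytest.approx(
            imp.table.loc["c2", "importance"])


class TestFairness:
    def test_bin_edges(self, rng):
        y = np.zeros(4)
        p = np.ones(4)
        ages = [39, 40, 19, 82]
        table = fairness_report(y, p, ages, ["m", "f", "m", "f"])
        by_group = table.set_index("group")
        assert by_group.loc["19-39", "n"] == 2  # ages 39 and 19
        assert by_group.loc["40-59", "n"] == 1  # age 40
        assert by_group.loc["60-82", "n"] == 1

    def test_group_rmse_matches_subset(self, rng):
        n = 40
        y = rng.uniform(0, 4, n)
        p = y + rng.normal(0, 0.5, n)
        age = rng.integers(19, 83, n)
        sex = rng.choice(["m", "f"], n)
        table = fairness_report(y, p, age, sex).set_index("group")
        m = sex == "m"
        expected = regression_metrics(y[m], p[m]).rmse
        assert table.loc["male", "rmse"] == pytest.approx(expected)

    def test_empty_group_is_missing(self):
        table = fairness_report([0, 1], [0, 1], [25, 30], ["m", "m"])
        assert np.isnan(table.set_index("group").loc["female", "rmse"])


class TestConfounder:
    def test_deterministic_relation(self):
        age = np.array([20.0, 30, 40, 50])
        assert confounder_association(age, 2 * age) == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        age = rng.uniform(19, 82, size=2000)
        score = rng.uniform(0, 4, size=2000)
        assert abs(confounder_association(age, score)) < 0.01

    def test_affine_invariance(self, rng):
        age = rng.uniform(19, 82, size=50)
        score = 0.05 * age + rng.normal(0, 0.5, size=50)
        r2 = confounder_association(age, score)
        assert confounder_association(3 * age + 7, score) == pytest.approx(
            r2, rel=1e-9)
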