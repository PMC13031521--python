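"""Scoring, neighbor-class separation, attribution aggregation, fairness.

Regression experiments are scored with RMSE and R² (plus per-true-score
RMSE); classification with macro/weighted F1, macro precision/recall and
Cohen's κ.  Whether adjacent severity grades are separated by the regression
outputs is tested with a two-sided Mann-Whitney U test (exact for small
groups, tie-corrected normal approximation otherwise), uncorrected across
pairs.  Per-sample tree attributions are folded into a per-channel
importance ranking, and group-wise RMSE tables quantify fairness across sex
and age groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
)

from .errors import (
    EmptyInputError,
    InvalidArgumentError,
    SchemaError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

AGE_BINS: tuple[tuple[int, int], ...] = ((19, 39), (40, 59), (60, 82))


@dataclass
class MetricReport:
    """Union container for regression and classification scores."""

    rmse: float | None = None
    r2: float | None = None
    per_score_rmse: dict[float, float] = field(default_factory=dict)
    macro_f1: float | None = None
    weighted_f1: float | None = None
    macro_precision: float | None = None
    macro_recall: float | None = None
    kappa: float | None = None
    per_class_f1: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if v is not None}
        out["per_score_rmse"] = {str(k): v for k, v in self.per_score_rmse.items()}
        out["per_class_f1"] = {str(k): v for k, v in self.per_class_f1.items()}
        return out


def regression_metrics(y_true, y_pred) -> MetricReport:
    """RMSE, R² and per-true-score-level RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise InvalidArgumentError("length mismatch")
    if len(y_true) < 2:
        raise EmptyInputError("need at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("zero-variance truth: R² undefined")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    per_score = {}
    for level in np.unique(y_true):
        m = y_true == level
        per_score[float(level)] = float(
            np.sqrt(np.mean((y_true[m] - y_pred[m]) ** 2)))
    return MetricReport(rmse=rmse, r2=r2, per_score_rmse=per_score,
                        n=len(y_true))


def classification_metrics(y_true, y_pred) -> MetricReport:
    """Macro/weighted F1, macro precision/recall and Cohen's κ.

    κ and the macro averages are computed over the union of labels observed
    in truth or prediction; macro-F1 is by construction the unweighted mean
    of the per-class F1 scores.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise EmptyInputError("empty input")
    if len(y_true) != len(y_pred):
        raise InvalidArgumentError("length mismatch")
    labels = sorted(set(y_true) | set(y_pred), key=str)
    per_class = f1_score(y_true, y_pred, labels=labels, average=None,
                         zero_division=0)
    return MetricReport(
        macro_f1=float(np.mean(per_class)),
        weighted_f1=float(f1_score(y_true, y_pred, labels=labels,
                                   average="weighted", zero_division=0)),
        macro_precision=float(precision_score(y_true, y_pred, labels=labels,
                                              average="macro",
                                              zero_division=0)),
        macro_recall=float(recall_score(y_true, y_pred, labels=labels,
                                        average="macro", zero_division=0)),
        kappa=float(cohen_kappa_score(y_true, y_pred, labels=labels)),
        per_class_f1={lab: float(v) for lab, v in zip(labels, per_class)},
        n=len(y_true),
    )


# ---------------------------------------------------------------------------
# Neighbor-class separation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeighborTest:
    """Mann-Whitney U test between the predictions of two adjacent grades."""

    pair: tuple
    u_statistic: float
    p_value: float
    n1: int
    n2: int


def mann_whitney_u(lower_group, upper_group, exact_max_n: int = 8
                   ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with the pinned convention.

    U counts the (x, y) pairs with x < y plus half the ties, for x from the
    lower-class group and y from the upper-class group.  The p-value is
    exact (full-permutation) when both groups have at most ``exact_max_n``
    observations and there are no ties; otherwise the tie-corrected normal
    approximation is used.
    """
    x = np.asarray(lower_group, dtype=float)
    y = np.asarray(upper_group, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise EmptyInputError("both groups must be non-empty")
    # scipy's statistic counts x > y pairs (+ ties/2); mirror it
    u_less = float(np.sum(x[:, None] < y[None, :])
                   + 0.5 * np.sum(x[:, None] == y[None, :]))
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = ("exact" if len(x) <= exact_max_n and len(y) <= exact_max_n
              and not has_ties else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return u_less, float(res.pvalue)


def neighbor_separation(predictions_by_class: dict) -> list[NeighborTest]:
    """Mann-Whitney tests over all adjacent class pairs.

    ``predictions_by_class`` maps an orderable class key to the regression
    outputs of videos truly in that class.  P-values are reported
    uncorrected.  Pairs with an empty group are skipped with a log line.
    """
    keys = sorted(predictions_by_class)
    tests = []
    for lo, hi in zip(keys[:-1], keys[1:]):
        a, b = predictions_by_class[lo], predictions_by_class[hi]
        if len(a) == 0 or len(b) == 0:
            logger.warning("pair (%s, %s): empty group; skipped", lo, hi)
            continue
        u, p = mann_whitney_u(a, b)
        tests.append(NeighborTest(pair=(lo, hi), u_statistic=u, p_value=p,
                                  n1=len(a), n2=len(b)))
    return tests


# ---------------------------------------------------------------------------
# Attribution aggregation
# ---------------------------------------------------------------------------


@dataclass
class ChannelImportance:
    """Per-channel mean absolute attribution, ranked descending."""

    table: pd.DataFrame  # index: channel; columns: importance, category, rank

    @property
    def ranking(self) -> list[str]:
        return list(self.table.index)


def aggregate_attributions(attributions: pd.DataFrame,
                           provenance: pd.DataFrame) -> ChannelImportance:
    """Fold per-feature attributions into per-channel importances.

    ``attributions``: samples x features (out-of-fold attribution rows,
    pooled across folds).  Each feature's importance is the mean absolute
    attribution over samples; channel importance is the sum over that
    channel's features, so channel sums conserve the total feature
    importance exactly.
    """
    missing = [c for c in attributions.columns if c not in provenance.index]
    if missing:
        raise SchemaError(f"features without provenance: {missing[:5]}")
    per_feature = attributions.abs().mean(axis=0)
    prov = provenance.loc[per_feature.index]
    table = (pd.DataFrame({"importance": per_feature,
                           "channel": prov["channel"],
                           "category": prov["category"]})
             .groupby(["channel", "category"], sort=False)["importance"]
             .sum().reset_index(level="category"))
    table = table.sort_values("importance", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    return ChannelImportance(table=table)


# ---------------------------------------------------------------------------
# Fairness and confounders
# ---------------------------------------------------------------------------


def fairness_report(y_true, y_pred, age, sex) -> pd.DataFrame:
    """Group-wise RMSE per sex and per age bin (19–39, 40–59, 60–82).

    Bins are closed on both ends; empty groups are reported with NaN RMSE
    rather than zero.  Returns a tidy table (group_type, group, n, rmse).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    rows = []
    for value in ("m", "f"):
        m = sex == value
        rows.append(("sex", "male" if value == "m" else "female", int(m.sum()),
                     _subset_rmse(y_true, y_pred, m)))
    for lo, hi in AGE_BINS:
        m = (age >= lo) & (age <= hi)
        rows.append(("age", f"{lo}-{hi}", int(m.sum()),
                     _subset_rmse(y_true, y_pred, m)))
    return pd.DataFrame(rows, columns=["group_type", "group", "n", "rmse"])


def _subset_rmse(y_true, y_pred, mask) -> float:
    if mask.sum() == 0:
        return float("nan")
    return float(np.sqrt(np.mean((y_true[mask] - y_pred[mask]) ** 2)))


def confounder_association(age, scores) -> float:
    """R² of a univariate linear fit of score on age.

    A small value relative to the model's R² indicates age is not a usable
    shortcut for the score.
    """
    age = np.asarray(age, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(age) < 3:
        raise EmptyInputError("need at least 3 samples")
    if np.var(age) == 0:
        raise UndefinedStatisticError("zero age variance")
    slope, intercept = np.polyfit(age, scores, 1)
    fitted = slope * age + intercept
    ss_tot = float(np.sum((scores - scores.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("zero score variance")
    return 1.0 - float(np.sum((scores - fitted) ** 2)) / ss_tot
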