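"""Longitudinal trend analysis of gait features.

For a follow-up cohort, each feature (and the clinical score itself) is
normalized to each patient's baseline visit as a *relative* change,
``(v_t − v_0) / max(|v_0|, ε)``, then pooled across patients and correlated
with time (days since baseline).  Significance comes from the Wald test on
the slope of a univariate linear regression; the per-analysis family of
p-values is corrected with the Benjamini-Hochberg step-up; uncertainty on
Pearson's r comes from a patient-level bootstrap (patients are resampled
with replacement so that within-patient dependence travels with them).
Stage-stratified variants repeat the analysis within baseline-grade
sub-cohorts, and a linear mixed model (per-patient random intercept) relates
features to the clinical score over time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidArgumentError,
    MissingBaselineError,
    UndefinedStatisticError,
    UnstableCIError,
)

logger = logging.getLogger(__name__)

EPS_BASELINE: float = 1e-8


@dataclass(frozen=True)
class TrendResult:
    """Longitudinal statistics of one feature."""

    feature: str
    r: float
    p_raw: float
    spearman: float
    r2: float
    n: int
    ci_lo: float | None = None
    ci_hi: float | None = None
    p_bh: float | None = None


# ---------------------------------------------------------------------------
# Baseline normalization
# ---------------------------------------------------------------------------


def normalize_trajectory(values, mode: str = "relative",
                         eps: float = EPS_BASELINE
                         ) -> tuple[np.ndarray, bool]:
    """Normalize one patient's trajectory to its first (baseline) value.

    ``relative`` mode: (v_t − v_0) / max(|v_0|, eps); ``difference`` mode:
    v_t − v_0.  Returns the normalized values (baseline maps to 0 exactly)
    and an instability flag, set when the baseline magnitude fell below the
    ε guard in relative mode.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise MissingBaselineError("empty trajectory")
    v0 = v[0]
    if mode == "difference":
        return v - v0, False
    if mode != "relative":
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    unstable = abs(v0) < eps
    out = (v - v0) / max(abs(v0), eps)
    if unstable:
        logger.warning("baseline magnitude < %.0e: relative change is "
                       "numerically unstable", eps)
    return out, unstable


def baseline_normalize(df: pd.DataFrame, feature_cols: list[str],
                       patient_col: str = "patient_id",
                       day_col: str = "visit_day",
                       mode: str = "relative") -> pd.DataFrame:
    """Normalize every feature column to each patient's baseline visit.

    The baseline is the visit with the smallest day offset, which must be 0.
    Returns a copy with normalized feature columns and an ``unstable``
    indicator column; raises :class:`MissingBaselineError` naming the first
    patient without a day-0 visit.
    """
    out = df.sort_values([patient_col, day_col]).reset_index(drop=True).copy()
    out["unstable"] = False
    for pid, grp in out.groupby(patient_col, sort=False):
        if grp[day_col].iloc[0] != 0:
            raise MissingBaselineError(
                f"patient {pid!r} has no baseline (day 0) visit")
        for col in feature_cols:
            normed, unstable = normalize_trajectory(grp[col].to_numpy(), mode)
            out.loc[grp.index, col] = normed
            if unstable:
                out.loc[grp.index, "unstable"] = True
    return out


# ---------------------------------------------------------------------------
# Trends
# ---------------------------------------------------------------------------


def feature_time_trend(days, values, feature: str = "") -> TrendResult:
    """Pearson r of value vs. time plus the regression Wald-test p.

    Pools all (day offset, normalized value) pairs; the p-value is the
    t/Wald test on the slope of the univariate OLS fit (identical to the
    test on r).  Spearman's ρ and the fit R² are reported as companions.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(d) < 3:
        raise UndefinedStatisticError("need at least 3 points for a trend")
    if np.var(d) == 0 or np.var(v) == 0:
        raise UndefinedStatisticError("zero variance in time or value axis")
    fit = stats.linregress(d, v)
    rho = stats.spearmanr(d, v).statistic
    return TrendResult(feature=feature, r=float(fit.rvalue),
                       p_raw=float(fit.pvalue), spearman=float(rho),
                       r2=float(fit.rvalue ** 2), n=len(d))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} (p_(j) · m / j) over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def bootstrap_ci(df: pd.DataFrame, value_col: str,
                 patient_col: str = "patient_id", day_col: str = "visit_day",
                 n_resamples: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Patient-level bootstrap CI for Pearson's r of value vs. time.

    Patients are resampled with replacement and all their visits travel
    together; r is recomputed per resample and the (1−level)/2 percentiles
    reported.  Resamples with zero variance on either axis are skipped; if
    more than half are degenerate the interval is refused.
    """
    patients = df[patient_col].unique()
    if len(patients) < 3:
        raise UndefinedStatisticError("need at least 3 patients to bootstrap")
    groups = {p: g[[day_col, value_col]].to_numpy(dtype=float)
              for p, g in df.groupby(patient_col)}
    rng = np.random.default_rng(seed)
    rs = []
    degenerate = 0
    for _ in range(n_resamples):
        chosen = rng.choice(patients, size=len(patients), replace=True)
        data = np.concatenate([groups[p] for p in chosen])
        if np.var(data[:, 0]) == 0 or np.var(data[:, 1]) == 0:
            degenerate += 1
            continue
        rs.append(stats.pearsonr(data[:, 0], data[:, 1]).statistic)
    if degenerate > n_resamples / 2:
        raise UnstableCIError(
            f"{degenerate}/{n_resamples} bootstrap resamples degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(rs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def trend_table(df: pd.DataFrame, feature_cols: list[str],
                patient_col: str = "patient_id", day_col: str = "visit_day",
                n_resamples: int = 0, seed: int = 0) -> pd.DataFrame:
    """Per-feature trend statistics with BH correction across the family.

    Input must already be baseline-normalized.  Features whose trend is
    undefined (zero variance) are reported with NaN statistics and excluded
    from the BH family.  With ``n_resamples`` > 0, bootstrap CIs are added.
    Rows are sorted by |r| descending.
    """
    rows = []
    for col in feature_cols:
        try:
            tr = feature_time_trend(df[day_col], df[col], feature=col)
        except UndefinedStatisticError:
            logger.warning("feature %s: trend undefined; reported as missing",
                           col)
            rows.append({"feature": col, "r": np.nan, "p_raw": np.nan,
                         "spearman": np.nan, "r2": np.nan,
                         "n": int(df[col].notna().sum()),
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        row = {"feature": col, "r": tr.r, "p_raw": tr.p_raw,
               "spearman": tr.spearman, "r2": tr.r2, "n": tr.n,
               "ci_lo": np.nan, "ci_hi": np.nan}
        if n_resamples > 0:
            row["ci_lo"], row["ci_hi"] = bootstrap_ci(
                df, col, patient_col, day_col, n_resamples, seed)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    defined = table["p_raw"].notna()
    table["p_bh"] = np.nan
    if defined.any():
        table.loc[defined, "p_bh"] = bh_adjust(table.loc[defined, "p_raw"])
    return table.sort_values("r", key=np.abs, ascending=False, na_position="last")


def stage_stratified_top_features(
    df: pd.DataFrame, feature_cols: list[str],
    patient_col: str = "patient_id", day_col: str = "visit_day",
    grade_col: str = "baseline_grade", strata: tuple[int, ...] = (0, 1, 2, 3),
    min_patients: int = 2, n_resamples: int = 0, seed: int = 0,
) -> dict[str, pd.DataFrame | str]:
    """Overall and per-baseline-grade trend rankings.

    Runs :func:`trend_table` on the full cohort and within each baseline
    grade stratum, applying BH within each analysis family separately.
    Strata with fewer than ``min_patients`` patients map to the string
    ``"insufficient"`` instead of a table.
    """
    results: dict[str, pd.DataFrame | str] = {
        "overall": trend_table(df, feature_cols, patient_col, day_col,
                               n_resamples, seed)
    }
    for grade in strata:
        sub = df[df[grade_col] == grade]
        if sub[patient_col].nunique() < min_patients:
            logger.warning("stratum %s: < %d patients; insufficient",
                           grade, min_patients)
            results[f"grade_{grade}"] = "insufficient"
            continue
        results[f"grade_{grade}"] = trend_table(
            sub, feature_cols, patient_col, day_col, n_resamples, seed)
    return results


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------


def mixed_model_trend(df: pd.DataFrame, feature_cols: list[str],
                      score_col: str = "score",
                      patient_col: str = "patient_id") -> pd.DataFrame:
    """Linear mixed model of score on each feature, per-patient intercept.

    Per feature: ``score ~ feature`` with a random intercept grouped by
    patient; the fixed-effect slope and its Wald p are reported, BH applied
    across the feature family.  Non-converging fits are flagged and excluded
    from the ranking.  Rows are sorted by adjusted p.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    rows = []
    for col in feature_cols:
        sub = df[[score_col, col, patient_col]].dropna()
        if sub[patient_col].nunique() < 2:
            rows.append({"feature": col, "slope": np.nan, "p_raw": np.nan,
                         "converged": False})
            continue
        endog = sub[score_col].to_numpy(dtype=float)
        exog = sm.add_constant(sub[[col]].to_numpy(dtype=float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(endog, exog,
                                groups=sub[patient_col].to_numpy())
                res = model.fit(reml=False, method="lbfgs", maxiter=200)
            slope = float(res.fe_params[1])
            p_raw = float(res.pvalues[1])
            converged = bool(res.converged) and np.isfinite(p_raw)
            if not np.isfinite(p_raw):
                raise np.linalg.LinAlgError("degenerate mixed fit")
        except (np.linalg.LinAlgError, ValueError) as exc:
            # a vanishing random-intercept variance makes the mixed fit
            # singular; the model then degenerates to ordinary least squares
            logger.warning("feature %s: mixed model singular (%s); "
                           "OLS fallback", col, exc)
            ols = sm.OLS(endog, exog).fit()
            slope = float(ols.params[1])
            p_raw = float(ols.pvalues[1])
            converged = np.isfinite(p_raw)
        rows.append({"feature": col, "slope": slope, "p_raw": p_raw,
                     "converged": converged})
    table = pd.DataFrame(rows).set_index("feature")
    ok = table["converged"] & table["p_raw"].notna()
    table["p_bh"] = np.nan
    if ok.any():
        table.loc[ok, "p_bh"] = bh_adjust(table.loc[ok, "p_raw"])
    return table.sort_values("p_bh", na_position="last")


def top_mixed_model_features(table: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Top-k converged features by BH-adjusted p."""
    return table[table["converged"]].nsmallest(k, "p_bh")
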