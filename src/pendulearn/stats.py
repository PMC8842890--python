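"""Factorial statistics for the training / retention contrasts.

The analysis works on per-participant contrasts of the block metrics:

* training effect: mean of the 20 training blocks minus mean of the 4 catch
  trials (T - CT), which removes an approximately linear learning trend
  because the catch trials sit symmetrically in the training sequence;
* learning: short-/long-term retention minus baseline (STR - BL, LTR - BL),
  each end averaged over its two blocks; transfer learning uses the
  transfer-baseline and transfer-retention blocks.

Each contrast is then tested in the 2x2 between-subjects design (haptic
rendering x weight support).  Normality of the contrast values is checked
with a one-sample Kolmogorov-Smirnov test on the standardised cell residuals
at alpha = 0.05; normal data get a two-way ANOVA (type III on the balanced
design), non-normal data fall back to two Kruskal-Wallis tests (one per
factor, no interaction).  A significant interaction is followed by four
Bonferroni-corrected pairwise comparisons (each factor within each level of
the other).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .exceptions import (DataCompletenessError, DesignError,
                         InsufficientDataError)

__all__ = [
    "StatResult",
    "ALPHA",
    "training_contrast",
    "retention_contrast",
    "factorial_test",
    "interaction_posthoc",
    "phase_score_correlation",
    "learning_curve_compare",
    "transfer_kinematics_mixed_anova",
    "score_questionnaire",
    "questionnaire_subscale_table",
    "baseline_anova",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, degrees of freedom, p-value."""

    test: str            # "anova", "kruskal", "ttest", "pearson", "f-test"
    effect: str          # e.g. "HR", "WS", "HR x WS"
    statistic: float
    df: tuple            # degrees of freedom, () where not applicable
    p: float
    correction: Optional[str] = None
    normal: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p < ALPHA)


def _per_participant_mean(table: pd.DataFrame, metric: str,
                          phases: tuple) -> pd.Series:
    sub = table[table["phase"].isin(phases)]
    return sub.groupby("participant")[metric].mean()


def _participant_factors(table: pd.DataFrame) -> pd.DataFrame:
    cols = ["participant", "hr_train", "ws_train", "group"]
    cols = [c for c in cols if c in table.columns]
    return table[cols].drop_duplicates().set_index("participant")


def training_contrast(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-participant T - CT contrast of one metric.

    Requires the full training phase (20 T and 4 CT blocks per participant).
    Returns a frame indexed by participant with the factor columns and a
    ``value`` column.
    """
    counts = table[table["phase"].isin(["T", "CT"])].groupby(
        ["participant", "phase"]).size().unstack(fill_value=0)
    if (counts.get("T", pd.Series(dtype=int)) != 20).any() or (
            counts.get("CT", pd.Series(dtype=int)) != 4).any():
        raise DataCompletenessError(
            "every participant needs 20 T and 4 CT blocks")
    t_mean = _per_participant_mean(table, metric, ("T",))
    ct_mean = _per_participant_mean(table, metric, ("CT",))
    out = _participant_factors(table)
    out["value"] = t_mean - ct_mean
    if out["value"].isna().any():
        raise DataCompletenessError(f"missing {metric} values in T/CT blocks")
    return out


def retention_contrast(table: pd.DataFrame, metric: str,
                       endpoint: str = "STR",
                       baseline: str = "BL") -> pd.DataFrame:
    """Per-participant endpoint - baseline contrast (two blocks each side).

    ``endpoint`` is one of STR/LTR/TSTR/TLTR and ``baseline`` BL or TBL; the
    transfer variant pairs TSTR/TLTR with TBL.
    """
    for phase in (endpoint, baseline):
        counts = table[table["phase"] == phase].groupby("participant").size()
        if counts.empty or (counts != 2).any():
            raise DataCompletenessError(
                f"every participant needs exactly 2 {phase} blocks")
    end_mean = _per_participant_mean(table, metric, (endpoint,))
    base_mean = _per_participant_mean(table, metric, (baseline,))
    out = _participant_factors(table)
    out["value"] = end_mean - base_mean
    if out["value"].isna().any():
        raise DataCompletenessError(
            f"missing {metric} values in {endpoint}/{baseline} blocks")
    return out


def _twoway_anova(values: np.ndarray, hr: np.ndarray,
                  ws: np.ndarray) -> list:
    df = pd.DataFrame({"value": values,
                       "hr": pd.Categorical(hr),
                       "ws": pd.Categorical(ws)})
    model = smf.ols("value ~ C(hr, Sum) * C(ws, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    rows = []
    for effect, key in (("HR", "C(hr, Sum)"), ("WS", "C(ws, Sum)"),
                        ("HR x WS", "C(hr, Sum):C(ws, Sum)")):
        rows.append(StatResult(
            test="anova", effect=effect,
            statistic=float(table.loc[key, "F"]),
            df=(int(table.loc[key, "df"]),
                int(table.loc["Residual", "df"])),
            p=float(table.loc[key, "PR(>F)"]),
            normal=True))
    return rows


def _residual_normality_p(values: np.ndarray, hr: np.ndarray,
                          ws: np.ndarray) -> float:
    """One-sample KS p-value of the standardised 2x2 cell residuals."""
    df = pd.DataFrame({"value": values, "hr": hr, "ws": ws})
    resid = df["value"] - df.groupby(["hr", "ws"])["value"].transform("mean")
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return 0.0  # degenerate: treat as non-normal
    z = (resid - resid.mean()) / sd
    return float(sps.kstest(z, "norm").pvalue)


def factorial_test(values, hr, ws, alpha: float = ALPHA) -> list:
    """2x2 between-subjects test battery on per-participant contrasts.

    Runs the KS normality check, then either the two-way ANOVA (main effects
    + interaction) or, for non-normal data, two Kruskal-Wallis tests (HR and
    WS main effects only).  Returns a list of :class:`StatResult`.
    """
    values = np.asarray(values, dtype=float)
    hr = np.asarray(hr).astype(bool)
    ws = np.asarray(ws).astype(bool)
    if values.size != hr.size or values.size != ws.size:
        raise DesignError("values and factors must have equal length")
    for a in (False, True):
        for b in (False, True):
            if np.sum((hr == a) & (ws == b)) < 2:
                raise DesignError("every 2x2 cell needs at least 2 subjects")
    if np.ptp(values) == 0:
        # constant response: no between-group variability, nothing to reject
        return [StatResult(test="anova", effect=e, statistic=0.0,
                           df=(1, values.size - 4), p=1.0, normal=None)
                for e in ("HR", "WS", "HR x WS")]
    ks_p = _residual_normality_p(values, hr, ws)
    if ks_p >= alpha:
        return _twoway_anova(values, hr, ws)
    results = []
    for effect, factor in (("HR", hr), ("WS", ws)):
        groups = [values[factor], values[~factor]]
        try:
            h, p = sps.kruskal(*groups)
        except ValueError:  # all values identical within the comparison
            h, p = 0.0, 1.0
        results.append(StatResult(test="kruskal", effect=effect,
                                  statistic=float(h), df=(1,), p=float(p),
                                  normal=False))
    return results


def interaction_posthoc(values, hr, ws) -> list:
    """Four Bonferroni-corrected pairwise comparisons after an interaction.

    HR effect within each WS level and WS effect within each HR level, as
    Welch-free two-sample t-tests with the adjusted p = min(1, 4*p_raw).
    """
    values = np.asarray(values, dtype=float)
    hr = np.asarray(hr).astype(bool)
    ws = np.asarray(ws).astype(bool)
    comparisons = [
        ("HR | WS:OFF", values[hr & ~ws], values[~hr & ~ws]),
        ("HR | WS:ON", values[hr & ws], values[~hr & ws]),
        ("WS | HR:OFF", values[~hr & ws], values[~hr & ~ws]),
        ("WS | HR:ON", values[hr & ws], values[hr & ~ws]),
    ]
    results = []
    for label, a, b in comparisons:
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b)
        results.append(StatResult(
            test="ttest", effect=label, statistic=float(t),
            df=(a.size + b.size - 2,), p=float(min(1.0, 4.0 * p)),
            correction="bonferroni(4)"))
    return results


def phase_score_correlation(table: pd.DataFrame,
                            endpoint: str = "BL") -> StatResult:
    """Pearson correlation of |phase difference| with score at a test phase.

    Each participant contributes one point: the phase-endpoint means of
    ``phase_diff`` (absolute value taken after averaging) and ``score``.
    """
    phase = _per_participant_mean(table, "phase_diff", (endpoint,))
    score = _per_participant_mean(table, "score", (endpoint,))
    joined = pd.concat([phase.abs().rename("absphase"),
                        score.rename("score")], axis=1).dropna()
    if len(joined) < 3:
        raise InsufficientDataError(
            "need at least 3 participants for a correlation")
    r, p = sps.pearsonr(joined["absphase"], joined["score"])
    return StatResult(test="pearson", effect=f"|phase| vs score @ {endpoint}",
                      statistic=float(r), df=(len(joined) - 2,), p=float(p))


def learning_curve_compare(blocks, scores) -> StatResult:
    """Nested-model test of a logarithmic term in the learning curve.

    Fits ``score ~ block`` and ``score ~ block + log(block)`` by ordinary
    least squares (block numbers pooled over whatever series are passed) and
    reports the F-test of the nonlinear term's improvement.  A significant
    result indicates the learning curve saturates rather than staying linear.
    """
    blocks = np.asarray(blocks, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if blocks.size != scores.size:
        raise ValueError("blocks and scores must have equal length")
    if blocks.size < 10:
        raise InsufficientDataError("need at least 10 blocks")
    if np.any(blocks <= 0):
        raise ValueError("block numbers must be positive (log term)")
    x_lin = sm.add_constant(blocks)
    x_log = sm.add_constant(np.column_stack([blocks, np.log(blocks)]))
    fit_lin = sm.OLS(scores, x_lin).fit()
    fit_log = sm.OLS(scores, x_log).fit()
    df_num = 1
    df_den = int(fit_log.df_resid)
    if fit_log.ssr <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (fit_lin.ssr - fit_log.ssr) / df_num / (fit_log.ssr / df_den)
        f_stat = max(0.0, float(f_stat))
        p = float(sps.f.sf(f_stat, df_num, df_den))
    return StatResult(test="f-test", effect="log(block) term",
                      statistic=f_stat, df=(df_num, df_den), p=p)


def transfer_kinematics_mixed_anova(table: pd.DataFrame,
                                    metric: str) -> list:
    """Mixed ANOVA: rod length (within) x training group (between) at LTR.

    ``table`` must contain the LTR and TLTR blocks; the within-subject factor
    is the rod length (long main rod vs short transfer rod), the
    between-subjects factor the training group.  Applied to movement
    variability or hand speed.
    """
    sub = table[table["phase"].isin(["LTR", "TLTR"])].copy()
    if sub.empty:
        raise DataCompletenessError("no LTR/TLTR blocks in table")
    sub["rod"] = np.where(sub["phase"] == "LTR", "long", "short")
    agg = sub.groupby(["participant", "group", "rod"], observed=True)[
        metric].mean().reset_index()
    pivot = agg.pivot(index="participant", columns="rod", values=metric)
    if pivot.isna().any().any():
        raise DataCompletenessError(
            "every participant needs both rod-length conditions at LTR")
    aov = pg.mixed_anova(data=agg, dv=metric, within="rod",
                         subject="participant", between="group")
    results = []
    label = {"group": "group (between)", "rod": "rod length (within)",
             "Interaction": "group x rod"}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for _, row in aov.iterrows():
        results.append(StatResult(
            test="mixed-anova", effect=label.get(row["Source"], row["Source"]),
            statistic=float(row["F"]),
            df=(int(row["DF1"]), int(row["DF2"])),
            p=float(row[p_col])))
    return results


def score_questionnaire(items) -> float:
    """Subscale mean of a 3-item Likert block, tolerating one missing item.

    With exactly one missing (NaN) item the mean of the remaining two is
    used; two or more missing items raise an error.
    """
    items = np.asarray(items, dtype=float)
    if items.size != 3:
        raise ValueError("a subscale has exactly 3 items")
    missing = np.isnan(items)
    if missing.sum() >= 2:
        raise DataCompletenessError(
            "subscale unusable: 2 or more missing items")
    return float(np.nanmean(items))


def questionnaire_subscale_table(questionnaires: pd.DataFrame) -> pd.DataFrame:
    """Per-participant subscale means at every time point (long format).

    Subscales with two or more missing items are reported as NaN so callers
    can drop them pairwise.
    """
    rows = []
    keys = ["participant", "group", "time_point", "subscale"]
    for key_vals, grp in questionnaires.groupby(keys, observed=True):
        try:
            value = score_questionnaire(
                grp.sort_values("item")["response"].values)
        except DataCompletenessError:
            value = np.nan
        rows.append(dict(zip(keys, key_vals)) | {"value": value})
    return pd.DataFrame(rows)


def baseline_anova(table: pd.DataFrame, metric: str) -> StatResult:
    """One-way ANOVA of the baseline (mean of the two BL blocks) by group."""
    base = table[table["phase"] == "BL"].groupby(
        ["participant", "group"], observed=True)[metric].mean().reset_index()
    groups = [g[metric].values for _, g in base.groupby("group",
                                                        observed=True)]
    if len(groups) < 2:
        raise DesignError("need at least two groups")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return StatResult(test="anova", effect=f"group @ BL ({metric})",
                      statistic=float(f), df=(k - 1, n - k), p=float(p))
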