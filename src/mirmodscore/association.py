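"""Association of signature scores with clinical covariates and survival.

Implements the cohort analyses: one-way ANOVA across ordered progression /
size / stage groups, paired tumor-normal comparison, Tukey post-hoc tables,
Pearson correlation with proliferation, and Kaplan-Meier / log-rank /
covariate-adjusted Cox comparison of the upper vs lower score quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class AssociationReport:
    test: str
    statistic: float
    p: float
    groups: pd.DataFrame | None = None       # n / mean / se per group
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def _aligned(scores: pd.DataFrame, clinical: ClinicalTable,
             score_col: str) -> pd.DataFrame:
    if score_col not in scores.columns:
        raise KeyError(f"score column {score_col!r} missing")
    common = scores.index.intersection(clinical.sample_ids)
    df = clinical.table.loc[common].copy()
    df["score"] = scores.loc[common, score_col]
    return df


def _group_summary(df: pd.DataFrame, by: str) -> pd.DataFrame:
    g = df.groupby(by, observed=True)["score"]
    return pd.DataFrame({
        "n": g.size(),
        "mean": g.mean(),
        "se": g.std(ddof=1) / np.sqrt(g.size()),
    })


def stage_trend(scores: pd.DataFrame, clinical: ClinicalTable,
                stage_field: str = "progression_stage",
                score_col: str = "general_score",
                levels=None) -> AssociationReport:
    """One-way ANOVA of scores across the ordered groups of ``stage_field``.

    Groups with fewer than 2 samples are excluded with a warning.  The
    per-group mean +/- SE summary mirrors the progression-trend panels.
    """
    df = _aligned(scores, clinical, score_col).dropna(subset=[stage_field, "score"])
    if levels is not None:
        df = df[df[stage_field].isin(levels)]
        order = [l for l in levels if l in set(df[stage_field])]
    else:
        order = sorted(df[stage_field].unique())
    arrays, used = [], []
    for lab in order:
        vals = df.loc[df[stage_field] == lab, "score"].to_numpy()
        if len(vals) < 2:
            logger.warning("group %r has <2 samples; excluded", lab)
            continue
        arrays.append(vals)
        used.append(lab)
    if len(arrays) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    f, p = stats.f_oneway(*arrays)
    summary = _group_summary(df[df[stage_field].isin(used)], stage_field).loc[used]
    return AssociationReport(test=f"one-way ANOVA across {stage_field}",
                             statistic=float(f), p=float(p), groups=summary)


def matched_comparison(scores: pd.DataFrame, clinical: ClinicalTable,
                       score_col: str = "impact_score") -> AssociationReport:
    """Paired t-test of normal minus tumor scores over complete matched pairs.

    Also summarizes the unmatched-tumor group for the three-bar layout
    (normal / matched tumor / unmatched tumor).  A zero-variance difference
    vector is reported as degenerate rather than an infinite t.
    """
    pairs = clinical.matched_pairs()
    valid = scores.index[scores[score_col].notna()]
    pairs = pairs[pairs["normal"].isin(valid) & pairs["tumor"].isin(valid)]
    if len(pairs) < 2:
        raise ValueError("need >=2 complete matched pairs")
    normal = scores.loc[pairs["normal"], score_col].to_numpy()
    tumor = scores.loc[pairs["tumor"], score_col].to_numpy()
    diff = normal - tumor
    degenerate = bool(np.std(diff, ddof=1) < 1e-12)
    if degenerate:
        t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.nan, np.nan)
        logger.warning("matched comparison degenerate: zero within-pair variance")
    else:
        t, p = stats.ttest_rel(normal, tumor)
    tumor_ids = clinical.table.index[
        (clinical.table.get("tissue") == "tumor")].intersection(scores.index)
    unmatched = tumor_ids.difference(pairs["tumor"])
    groups = pd.DataFrame({
        "n": [len(normal), len(tumor), len(unmatched)],
        "mean": [normal.mean(), tumor.mean(),
                 scores.loc[unmatched, score_col].mean() if len(unmatched) else np.nan],
        "se": [normal.std(ddof=1) / np.sqrt(len(normal)),
               tumor.std(ddof=1) / np.sqrt(len(tumor)),
               (scores.loc[unmatched, score_col].std(ddof=1) / np.sqrt(len(unmatched)))
               if len(unmatched) > 1 else np.nan],
    }, index=["normal", "tumor_matched", "tumor_unmatched"])
    return AssociationReport(test="paired t-test (normal - tumor)",
                             statistic=float(t), p=float(p), groups=groups,
                             extra={"n_pairs": len(pairs), "degenerate": degenerate})


def group_posthoc(scores: pd.DataFrame, clinical: ClinicalTable,
                  field: str, score_col: str = "impact_score",
                  levels=None) -> AssociationReport:
    """Omnibus one-way ANOVA plus all-pairs Tukey HSD over ``field`` groups."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = _aligned(scores, clinical, score_col).dropna(subset=[field, "score"])
    if levels is not None:
        df = df[df[field].isin(levels)]
    order = sorted(df[field].unique())
    if len(order) < 3:
        raise ValueError("post-hoc analysis needs >=3 groups")
    arrays = [df.loc[df[field] == lab, "score"].to_numpy() for lab in order]
    f, p = stats.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(df["score"].to_numpy(), df[field].to_numpy())
    posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return AssociationReport(test=f"one-way ANOVA + Tukey HSD across {field}",
                             statistic=float(f), p=float(p),
                             groups=_group_summary(df, field).loc[order],
                             posthoc=posthoc)


def proliferation_correlation(scores: pd.DataFrame, clinical: ClinicalTable,
                              score_col: str = "impact_score") -> AssociationReport:
    """Pearson correlation of scores with the proliferation column."""
    df = _aligned(scores, clinical, score_col).dropna(
        subset=["proliferation", "score"])
    if len(df) < 3:
        raise ValueError("need >=3 samples with both score and proliferation")
    r, p = stats.pearsonr(df["score"], df["proliferation"])
    return AssociationReport(test="Pearson correlation with proliferation",
                             statistic=float(r), p=float(p),
                             extra={"n": len(df)})


class _SkipCox(Exception):
    """Internal control flow: caller asked for KM/log-rank only."""


def km_estimate(times, events, label: str = "KM") -> pd.DataFrame:
    """Kaplan-Meier product-limit survival function (index = time)."""
    from lifelines import KaplanMeierFitter

    fitter = KaplanMeierFitter()
    fitter.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int),
               label=label)
    return fitter.survival_function_


def _quartile_membership(values: pd.Series, inclusive: bool = False):
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75])
    if inclusive:
        lq = values <= q1
        uq = values >= q3
    else:
        lq = values < q1
        uq = values > q3
    return lq, uq, float(q1), float(q3)


def survival_by_quartile(scores: pd.DataFrame, clinical: ClinicalTable,
                         covariates=(), score_col: str = "general_score",
                         min_events: int = 10, inclusive: bool = False,
                         fit_cox: bool = True):
    """KM curves, log-rank and covariate-adjusted Cox for score quartiles.

    Tumors are split at the empirical 25th/75th percentiles of the score
    (strict comparison by default; ``inclusive`` includes boundary ties).
    The Cox model regresses survival on upper-vs-lower-quartile membership
    plus the listed covariates (ordered categories, treatment-coded
    against their first level).  Returns ``(report, km_curves)`` where
    ``km_curves`` maps group name -> survival-function DataFrame.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    df = _aligned(scores, clinical, score_col).dropna(
        subset=["os_time", "os_event", "score"])
    if int(df["os_event"].sum()) < min_events:
        raise ValueError(
            f"only {int(df['os_event'].sum())} events; floor is {min_events}")
    lq, uq, q1, q3 = _quartile_membership(df["score"], inclusive)
    sub = df[lq | uq].copy()
    sub["uq"] = uq[lq | uq].astype(int)

    km_curves = {
        name: km_estimate(sub.loc[mask, "os_time"], sub.loc[mask, "os_event"],
                          label=name)
        for name, mask in (("LQ", sub["uq"] == 0), ("UQ", sub["uq"] == 1))
    }

    lr = logrank_test(sub.loc[sub["uq"] == 1, "os_time"],
                      sub.loc[sub["uq"] == 0, "os_time"],
                      event_observed_A=sub.loc[sub["uq"] == 1, "os_event"],
                      event_observed_B=sub.loc[sub["uq"] == 0, "os_event"])

    extra = {"q1": q1, "q3": q3, "n_lq": int((sub["uq"] == 0).sum()),
             "n_uq": int((sub["uq"] == 1).sum())}
    cox_df = sub[["os_time", "os_event", "uq"]].copy()
    for cov in covariates:
        if cov not in sub.columns:
            raise KeyError(f"covariate {cov!r} missing from clinical table")
        dummies = pd.get_dummies(sub[cov].astype("category"), prefix=cov,
                                 drop_first=True, dtype=float)
        cox_df = pd.concat([cox_df, dummies], axis=1)
    cox_df = cox_df.dropna()
    try:
        if not fit_cox:
            raise _SkipCox
        cph = CoxPHFitter()
        cph.fit(cox_df, duration_col="os_time", event_col="os_event")
        extra.update({
            "cox_log_hr": float(cph.params_["uq"]),
            "cox_hr": float(np.exp(cph.params_["uq"])),
            "cox_ci_low": float(np.exp(cph.confidence_intervals_.loc["uq"].iloc[0])),
            "cox_ci_high": float(np.exp(cph.confidence_intervals_.loc["uq"].iloc[1])),
            "cox_p": float(cph.summary.loc["uq", "p"]),
        })
    except _SkipCox:
        pass
    except Exception as err:  # convergence failure on degenerate strata
        logger.warning("Cox model did not converge: %s", err)
        extra["cox_error"] = str(err)

    groups = pd.DataFrame({
        "n": [extra["n_lq"], extra["n_uq"]],
        "events": [int(sub.loc[sub["uq"] == 0, "os_event"].sum()),
                   int(sub.loc[sub["uq"] == 1, "os_event"].sum())],
    }, index=["LQ", "UQ"])
    report = AssociationReport(test="log-rank UQ vs LQ + Cox adjustment",
                               statistic=float(lr.test_statistic),
                               p=float(lr.p_value), groups=groups, extra=extra)
    return report, km_curves


def bh_summary(reports: dict) -> pd.DataFrame:
    """BH-adjusted overview of a panel of association p-values."""
    from .integration import bh_adjust

    names = list(reports)
    p = [reports[n].p for n in names]
    return pd.DataFrame({"test": [reports[n].test for n in names],
                         "p": p, "q": bh_adjust(p)}, index=names)
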