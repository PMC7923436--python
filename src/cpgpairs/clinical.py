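"""Survival and clinicopathology statistics for the discovered subtypes:
Kaplan-Meier curves, k-group and pairwise log-rank tests, and chi-square
association between subtype and categorical clinical features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test
from scipy import stats


def filter_clinical(
    clinical: pd.DataFrame,
    min_followup: float = 30.0,
    required: tuple[str, ...] = ("grade", "stage", "T", "M"),
    unknown_tokens: tuple[str, ...] = ("unknown", "NA", "NX", "GX", ""),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort inclusion rules.

    Drops samples with follow-up time not strictly greater than
    ``min_followup`` days and samples with an unknown value in any of the
    ``required`` staging columns. Returns the filtered table and a report of
    how many samples each rule removed.
    """
    report: dict[str, int] = {}
    keep = clinical["time"] > min_followup
    report["short_followup"] = int((~keep).sum())
    out = clinical.loc[keep]
    for col in required:
        if col not in out.columns:
            continue
        bad = out[col].isna() | out[col].astype(str).isin(unknown_tokens)
        report[f"unknown_{col}"] = int(bad.sum())
        out = out.loc[~bad]
    return out, report


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit survival estimate."""

    times: np.ndarray  # event times, ascending
    survival: np.ndarray  # S(t) just after each event time

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of the survival function.

    S(0) = 1 and the estimator steps down only at observed event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    keep = t > 0
    return KaplanMeierCurve(times=t[keep], survival=s[keep])


def logrank_test(
    times, events, labels: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """k-group log-rank test plus all pairwise comparisons.

    Returns (chi-square statistic, degrees of freedom, p-value, pairwise
    table with columns group_a, group_b, chi2, p).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("a group has no observations")
    res = multivariate_logrank_test(times, groups, events)
    df = len(uniq) - 1
    pw = pairwise_logrank_test(times, groups, events)
    rows = [
        (a, b, float(pw.summary.loc[(a, b), "test_statistic"]),
         float(pw.summary.loc[(a, b), "p"]))
        for (a, b) in pw.summary.index
    ]
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "chi2", "p"])
    return float(res.test_statistic), df, float(res.p_value), pairwise


def chisq_association(
    feature: pd.Series, labels: pd.Series
) -> tuple[float, int, float, pd.DataFrame, bool]:
    """Pearson chi-square test of independence between a categorical feature
    and subtype labels, without continuity correction.

    Returns (chi2, df, p, expected-count table, low_expected flag); the flag
    is set when any expected cell count is below 5, where the chi-square
    approximation is unreliable.
    """
    common = feature.index.intersection(labels.index)
    table = pd.crosstab(feature.loc[common], labels.loc[common])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and >= 2 columns")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return float(chi2), int(df), float(p), expected, bool((expected.to_numpy() < 5).any())


def dichotomize_age(age: pd.Series, cut: float = 65.0) -> pd.Series:
    """Categorize age at a configurable cut (default <=65 vs >65 years)."""
    return pd.Series(
        np.where(age > cut, f">{cut:g}", f"<={cut:g}"), index=age.index, name="age_group"
    )
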