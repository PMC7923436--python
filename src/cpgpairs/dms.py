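"""Differential methylation: per-probe Wilcoxon rank-sum (Mann-Whitney) tests
between tumor and normal groups, Benjamini-Hochberg FDR, and a delta-beta
effect-size threshold.

A probe is called a differentially methylated site (DMS) when its BH-adjusted
p-value is below ``fdr_max`` AND the absolute difference of group mean beta
values exceeds ``delta_min`` (both strict inequalities).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# exact null enumeration is cheap up to this product of group sizes
_EXACT_MAX_PRODUCT = 400


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact null for small tie-free groups,
    tie-corrected normal approximation otherwise."""
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (len(x) * len(y) <= _EXACT_MAX_PRODUCT) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def wilcoxon_dms(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    fdr_max: float = 0.05,
    delta_min: float = 0.2,
) -> pd.DataFrame:
    """Test every probe for tumor-vs-normal differential methylation.

    Parameters
    ----------
    tumor, normal
        Beta matrices (probes x samples) over an identical probe set, fully
        imputed, with at least two samples per group.
    fdr_max, delta_min
        Selection thresholds: ``fdr < fdr_max`` and ``|deltabeta| > delta_min``.

    Returns
    -------
    DataFrame indexed by probe_id (sorted), with columns ``mean_tumor``,
    ``mean_normal``, ``deltabeta`` (tumor minus normal), ``p_value``, ``fdr``
    and boolean ``selected``.
    """
    t_set, n_set = set(tumor.index), set(normal.index)
    if t_set != n_set:
        diff = sorted(t_set.symmetric_difference(n_set))
        raise ValueError(f"tumor/normal probe sets differ: {diff[:10]}")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    probes = sorted(t_set)
    t = tumor.loc[probes].to_numpy(dtype=float)
    n = normal.loc[probes].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(n).any():
        raise ValueError("missing beta values: impute before testing")
    mean_t = t.mean(axis=1)
    mean_n = n.mean(axis=1)
    pvals = np.array([_mannwhitney_p(t[i], n[i]) for i in range(len(probes))])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    delta = mean_t - mean_n
    table = pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "deltabeta": delta,
            "p_value": pvals,
            "fdr": fdr,
            "selected": (fdr < fdr_max) & (np.abs(delta) > delta_min),
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return table


def selected_probes(dms_table: pd.DataFrame) -> list[str]:
    """Probe IDs flagged as differentially methylated, in index order."""
    return dms_table.index[dms_table["selected"]].tolist()
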