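"""Methylation-array preprocessing: promoter probe selection, probe-level
exclusion filters, and KNN imputation of missing beta values.

A beta matrix is a probes x samples :class:`pandas.DataFrame` of methylation
fractions in [0, 1]; missing values (NaN) are allowed before imputation.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 2000  # bp 5' of the TSS
PROMOTER_DOWNSTREAM = 500  # bp 3' of the TSS

_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "chrx", "chry", "x", "y", "23", "24"}


def validate_beta(beta: pd.DataFrame, allow_missing: bool = True) -> None:
    """Check the beta-matrix invariants: unique identifiers, values in [0, 1]."""
    if beta.index.has_duplicates:
        dupes = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe identifiers: {dupes[:5]}")
    if beta.columns.has_duplicates:
        dupes = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    values = beta.to_numpy(dtype=float)
    if not allow_missing and np.isnan(values).any():
        raise ValueError("beta matrix contains missing values")
    finite = values[~np.isnan(values)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta values outside [0, 1]")


def select_promoter_probes(
    annotation: pd.DataFrame, genes: Sequence[str]
) -> list[str]:
    """Return probes lying in the strand-aware promoter window of the given genes.

    The promoter is taken as 2 kb upstream to 0.5 kb downstream of the
    transcription start site: positions in ``[tss - 2000, tss + 500]`` for a
    gene on the + strand and ``[tss - 500, tss + 2000]`` on the - strand,
    1-based and inclusive at both ends.

    Parameters
    ----------
    annotation
        Columns ``probe_id``, ``chromosome``, ``position``, ``strand``,
        ``gene``, ``tss``.
    genes
        Gene symbols whose promoters to scan.

    Returns
    -------
    list of probe IDs, sorted.
    """
    bad = annotation.loc[~annotation["strand"].isin(["+", "-"])]
    if len(bad):
        probe = bad["probe_id"].iloc[0]
        raise ValueError(f"unknown strand {bad['strand'].iloc[0]!r} for probe {probe}")
    genes = set(genes)
    if not genes:
        return []
    sub = annotation.loc[annotation["gene"].isin(genes)]
    plus = sub["strand"] == "+"
    lo = np.where(plus, sub["tss"] - PROMOTER_UPSTREAM, sub["tss"] - PROMOTER_DOWNSTREAM)
    hi = np.where(plus, sub["tss"] + PROMOTER_DOWNSTREAM, sub["tss"] + PROMOTER_UPSTREAM)
    inside = (sub["position"] >= lo) & (sub["position"] <= hi)
    return sorted(sub.loc[inside, "probe_id"].unique().tolist())


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    cross_reactive: Sequence[str] = (),
    max_missing: float = 0.7,
) -> pd.DataFrame:
    """Apply the three probe exclusion rules.

    Removes probes (1) missing in strictly more than ``max_missing`` of the
    samples, (2) mapped to the X or Y chromosome, and (3) listed as
    cross-reactive. Samples are untouched. A probe missing in exactly
    ``max_missing`` of the samples is retained.
    """
    validate_beta(beta)
    chrom = annotation.set_index("probe_id")["chromosome"]
    missing_frac = beta.isna().mean(axis=1)
    on_sex = beta.index.map(lambda p: str(chrom.get(p, "")) in _SEX_CHROMS)
    in_xreact = beta.index.isin(set(cross_reactive))
    keep = (missing_frac <= max_missing) & ~on_sex.values & ~in_xreact
    out = beta.loc[keep]
    if out.empty:
        raise ValueError("no probes survived filtering")
    return out


def _pairwise_shared_sqdist(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance between probe rows over the samples observed
    in both rows. ``mask`` marks observed entries; missing entries are treated
    as absent, not zero."""
    filled = np.where(mask, values, 0.0)
    sq = filled**2
    w = mask.astype(float)
    # sum over shared columns of a_i^2, b_j^2 and a_i * b_j
    aa = sq @ w.T
    cross = filled @ filled.T
    return aa + aa.T - 2.0 * cross


def knn_impute(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing beta values from the k nearest probes.

    For a missing entry (probe, sample) the imputed value is the unweighted
    mean of that sample's values at the ``k`` probes nearest to the target
    probe, where distance is Euclidean over the samples observed in both
    probes and candidate neighbours must be observed in the target sample.
    Observed values are never altered and the output has no missing values.
    """
    validate_beta(beta)
    values = beta.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    if mask.all():
        return beta.copy()
    n_complete = int(mask.all(axis=1).sum())
    if k >= n_complete:
        raise ValueError(
            f"k={k} must be smaller than the number of complete probes ({n_complete})"
        )
    dist = _pairwise_shared_sqdist(values, mask)
    np.fill_diagonal(dist, np.inf)
    out = values.copy()
    rows_with_missing = np.flatnonzero(~mask.all(axis=1))
    for i in rows_with_missing:
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(~mask[i]):
            donors = order[mask[order, j]][:k]
            out[i, j] = values[donors, j].mean()
    result = pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return result.clip(0.0, 1.0)
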