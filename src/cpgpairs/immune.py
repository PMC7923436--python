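"""Single-sample gene-set enrichment (ssGSEA), ESTIMATE-style tumor
microenvironment scores, and between-subtype score comparisons.

The ssGSEA score of a gene set in one sample is the integrated difference
between two empirical cumulative distribution functions over the sample's
expression-ranked gene list: the in-set ECDF weighted by rank**alpha and the
uniform out-of-set ECDF. Because only within-sample ranks enter, the score is
invariant to any strictly increasing transform of that sample's expression.

The ESTIMATE score is the sum of the unnormalized ssGSEA scores of a stromal
and an immune signature; tumor purity is the published cosine transform
``cos(0.6049872018 + 0.0001467884 * ESTIMATE)``, a decreasing function of the
combined infiltration score.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884

CHECKPOINT_GENES = ["CD80", "CD86", "CD276", "CD274", "CTLA4", "PDCD1LG2", "PDCD1"]


def _ssgsea_sample(
    ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Enrichment score for one sample.

    ``ranks`` are within-sample expression ranks (largest expression = n),
    ``order`` indexes genes by decreasing expression, ``in_set`` flags set
    membership per gene.
    """
    flags = in_set[order]
    weights = np.abs(ranks[order]) ** alpha
    w_in = np.where(flags, weights, 0.0)
    total_in = w_in.sum()
    n_out = (~flags).sum()
    if total_in == 0 or n_out == 0:
        raise ValueError("gene set empty or spanning the whole universe")
    ecdf_in = np.cumsum(w_in) / total_in
    ecdf_out = np.cumsum(~flags) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(
    expr: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA scores for every gene set and sample.

    Parameters
    ----------
    expr
        Genes x samples non-negative expression matrix.
    sets
        Mapping of set name to gene symbols; each set must share at least one
        gene with the universe and must not cover it entirely.
    alpha
        Rank-weighting exponent of the in-set ECDF.
    normalize
        If True, divide all scores by the global (max - min) over the whole
        score matrix, the conventional cross-sample normalization.

    Returns
    -------
    Sets x samples DataFrame of enrichment scores.
    """
    genes = expr.index.to_numpy()
    universe = set(genes)
    memberships = {}
    for name, members in sets.items():
        hit = universe.intersection(members)
        if not hit:
            raise ValueError(f"gene set {name!r} has no genes in the universe")
        if len(hit) == len(universe):
            raise ValueError(f"gene set {name!r} covers the entire universe")
        memberships[name] = np.isin(genes, list(hit))
    values = expr.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    out = np.empty((len(memberships), n_samples))
    for j in range(n_samples):
        col = values[:, j]
        ranks = stats.rankdata(col)  # largest expression -> rank n
        order = np.argsort(-col, kind="stable")
        for i, in_set in enumerate(memberships.values()):
            out[i, j] = _ssgsea_sample(ranks, order, in_set, alpha)
    table = pd.DataFrame(out, index=list(memberships), columns=expr.columns)
    if normalize:
        rng = table.to_numpy().max() - table.to_numpy().min()
        if rng > 0:
            table = table / rng
    return table


def estimate_scores(
    expr: pd.DataFrame,
    stromal_set: Sequence[str],
    immune_set: Sequence[str],
) -> pd.DataFrame:
    """Stromal/immune/ESTIMATE scores and tumor purity per sample.

    Stromal and immune scores are unnormalized ssGSEA scores of the two
    signatures; the ESTIMATE score is their sum and purity its cosine
    transform (higher combined infiltration -> lower purity).
    """
    sig = ssgsea(expr, {"stromal": stromal_set, "immune": immune_set}, normalize=False)
    table = pd.DataFrame(
        {
            "stromal_score": sig.loc["stromal"],
            "immune_score": sig.loc["immune"],
        }
    )
    table["estimate_score"] = table["stromal_score"] + table["immune_score"]
    table["tumor_purity"] = purity_from_estimate(table["estimate_score"])
    return table


def purity_from_estimate(estimate_score):
    """Published cosine mapping from ESTIMATE score to tumor purity."""
    return np.cos(PURITY_INTERCEPT + PURITY_SLOPE * np.asarray(estimate_score, float))


def compare_groups(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis comparison of a per-sample scalar across subtypes.

    Returns the tie-corrected H statistic and its chi-square p-value on
    k - 1 degrees of freedom. Identical values in every group give H = 0,
    p = 1.
    """
    common = values.index.intersection(labels.index)
    values = values.loc[common]
    labels = labels.loc[common]
    groups = [values[labels == g].to_numpy(dtype=float) for g in sorted(labels.unique())]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def compare_sets_by_subtype(
    scores: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Kruskal-Wallis test per gene set (row) across subtype labels, with
    BH-adjusted p-values alongside the raw ones."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for name in scores.index:
        h, p = compare_groups(scores.loc[name], labels)
        rows.append((name, h, p))
    table = pd.DataFrame(rows, columns=["set", "H", "p_value"]).set_index("set")
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table


def checkpoint_expression(
    expr: pd.DataFrame, labels: pd.Series, genes: Sequence[str] = CHECKPOINT_GENES
) -> pd.DataFrame:
    """Per-checkpoint-gene Kruskal-Wallis comparison of raw expression across
    subtypes (per-gene framing rather than a set score)."""
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("no checkpoint genes found in the expression matrix")
    rows = []
    for g in present:
        h, p = compare_groups(expr.loc[g], labels)
        rows.append((g, h, p))
    return pd.DataFrame(rows, columns=["gene", "H", "p_value"]).set_index("gene")
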