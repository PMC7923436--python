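"""Per-subtype genomic alteration summaries: somatic mutation frequencies with
one-vs-rest contrasts from a MAF, and gene-level copy-number gain/loss calls
from segment means thresholded at +/-0.2.

Coordinate conventions: MAF and SEG records are 1-based with inclusive ends;
the gene model is 0-based half-open (BED-like). All overlap arithmetic
converts segments to 0-based half-open before intersecting.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# maftools-style non-coding / silent classes excluded from frequency counts
DEFAULT_SILENT_CLASSES = (
    "Silent",
    "Intron",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "IGR",
    "RNA",
)

GAIN_THRESHOLD = 0.2
LOSS_THRESHOLD = -0.2


def _mutated_matrix(
    maf: pd.DataFrame, silent_classes: Sequence[str]
) -> pd.DataFrame:
    coding = maf.loc[~maf["Variant_Classification"].isin(set(silent_classes))]
    mat = (
        coding.groupby(["Hugo_Symbol", "Tumor_Sample_Barcode"])
        .size()
        .unstack(fill_value=0)
        > 0
    )
    return mat


def mutation_frequency(
    maf: pd.DataFrame,
    labels: pd.Series,
    top_n: int = 30,
    silent_classes: Sequence[str] = DEFAULT_SILENT_CLASSES,
) -> tuple[pd.DataFrame, dict[int, list[str]], int]:
    """Per-cluster mutation frequency of every gene.

    Frequency is the fraction of the cluster's samples carrying at least one
    non-silent variant in the gene. Returns the gene x cluster frequency
    table, the per-cluster top-N gene lists (ties broken alphabetically), and
    the size of the union of those lists.
    """
    maf_samples = set(maf["Tumor_Sample_Barcode"])
    unlabeled = maf_samples - set(labels.index)
    if unlabeled:
        raise ValueError(f"MAF samples without a subtype label: {sorted(unlabeled)[:5]}")
    mutated = _mutated_matrix(maf, silent_classes)
    clusters = sorted(labels.unique())
    freq = pd.DataFrame(index=mutated.index, columns=clusters, dtype=float)
    for c in clusters:
        members = labels.index[labels == c]
        present = mutated.reindex(columns=members, fill_value=False)
        freq[c] = present.sum(axis=1) / len(members)
    top: dict[int, list[str]] = {}
    for c in clusters:
        ranked = freq[c].sort_index().sort_values(ascending=False, kind="stable")
        top[c] = ranked.head(top_n).index.tolist()
    union = len(set().union(*top.values())) if top else 0
    return freq, top, union


def _two_by_two_test(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square on a 2x2 table, substituting Fisher's exact test
    when any expected count is below 5. Returns (stat, p, fisher_used)."""
    if table.sum() == 0:
        return 0.0, 1.0, False
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return float("nan"), float(p), True
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), False


def compare_mutation(
    maf: pd.DataFrame,
    labels: pd.Series,
    gene: str,
    silent_classes: Sequence[str] = DEFAULT_SILENT_CLASSES,
) -> pd.DataFrame:
    """One-vs-rest mutation contrast for a gene, per cluster.

    For each cluster a 2x2 table (mutated/wild-type x in-cluster/rest) is
    tested with Pearson chi-square, falling back to Fisher's exact test at
    low expected counts (``fisher`` column flags the substitution).
    """
    mutated = _mutated_matrix(maf, silent_classes)
    if gene not in mutated.index:
        raise ValueError(f"gene {gene!r} has no non-silent variants in the MAF")
    status = mutated.loc[gene].reindex(labels.index, fill_value=False)
    rows = []
    for c in sorted(labels.unique()):
        in_c = labels == c
        table = np.array(
            [
                [(status & in_c).sum(), (status & ~in_c).sum()],
                [(~status & in_c).sum(), (~status & ~in_c).sum()],
            ]
        )
        chi2, p, fisher = _two_by_two_test(table)
        rows.append((c, status[in_c].mean(), status[~in_c].mean(), chi2, p, fisher))
    return pd.DataFrame(
        rows,
        columns=["cluster", "freq_in", "freq_rest", "chi2", "p", "fisher"],
    ).set_index("cluster")


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Check SEG invariants: start <= end, and no overlapping segments per
    sample and chromosome (warn and keep the first record on violation)."""
    if (segments["Start"] > segments["End"]).any():
        raise ValueError("segment with Start > End")
    keep_rows = []
    for (_, _), grp in segments.groupby(["Sample", "Chromosome"], sort=False):
        grp = grp.sort_values(["Start", "End"], kind="stable")
        last_end = -np.inf
        for idx, row in grp.iterrows():
            if row["Start"] <= last_end:
                import warnings

                warnings.warn(
                    f"overlapping segments for sample {row['Sample']} on "
                    f"{row['Chromosome']}; keeping the first",
                    stacklevel=2,
                )
                continue
            keep_rows.append(idx)
            last_end = row["End"]
    return segments.loc[keep_rows]


def gene_level_cnv(segments: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Reduce segments to one copy-number value per gene and sample.

    The value is the overlap-length-weighted mean of the segment means
    intersecting the gene body. Genes with no overlapping segment in a sample
    are missing (NaN). Invariant to the order of segment records.
    """
    segments = validate_segments(segments)
    samples = sorted(segments["Sample"].unique())
    genes = gene_model["gene"].tolist()
    if gene_model["gene"].duplicated().any():
        raise ValueError("duplicate gene symbols in the gene model")
    if (gene_model["start"] >= gene_model["end"]).any():
        raise ValueError("gene model requires start < end (0-based half-open)")
    out = pd.DataFrame(np.nan, index=genes, columns=samples)
    seg_by = {
        key: grp for key, grp in segments.groupby(["Sample", "Chromosome"], sort=False)
    }
    for _, g in gene_model.iterrows():
        g_start, g_end = int(g["start"]), int(g["end"])
        for s in samples:
            grp = seg_by.get((s, g["chromosome"]))
            if grp is None:
                continue
            # segments are 1-based inclusive -> half-open [Start-1, End)
            s0 = grp["Start"].to_numpy() - 1
            s1 = grp["End"].to_numpy()
            overlap = np.minimum(s1, g_end) - np.maximum(s0, g_start)
            hit = overlap > 0
            if hit.any():
                w = overlap[hit].astype(float)
                out.loc[g["gene"], s] = float(
                    np.average(grp["Segment_Mean"].to_numpy()[hit], weights=w)
                )
    if out.isna().all().all():
        raise ValueError("no gene overlaps any segment")
    return out


def call_gain_loss(values) -> tuple[np.ndarray | str, bool]:
    """Threshold copy-number values into {gain, neutral, loss}.

    Gain requires value > 0.2 and loss value < -0.2, both strict; anything
    between (including the thresholds) is neutral. Missing values are called
    neutral and flagged.
    """
    arr = np.asarray(values, dtype=float)
    missing = np.isnan(arr)
    calls = np.where(arr > GAIN_THRESHOLD, "gain", np.where(arr < LOSS_THRESHOLD, "loss", "neutral"))
    calls = np.where(missing, "neutral", calls)
    flagged = bool(missing.any())
    if np.ndim(values) == 0:
        return str(calls[()]), flagged
    return calls, flagged


def call_gain_loss_matrix(values: pd.DataFrame) -> pd.DataFrame:
    calls, _ = call_gain_loss(values.to_numpy())
    return pd.DataFrame(calls, index=values.index, columns=values.columns)


def compare_cnv(
    calls: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-vs-rest gain and loss contrasts for every gene and cluster.

    For each gene and cluster, a 2x2 test (gain vs not, and loss vs not,
    in-cluster vs pooled rest) via Pearson chi-square with Fisher fallback.
    Returns a long table with the per-contrast p-values and a ``significant``
    flag at ``alpha``.
    """
    missing = set(labels.index) - set(calls.columns)
    if missing:
        raise ValueError(f"labeled samples without CNV calls: {sorted(missing)[:5]}")
    calls = calls[labels.index]
    rows = []
    for c in sorted(labels.unique()):
        in_c = (labels == c).to_numpy()
        for gene in calls.index:
            gene_calls = calls.loc[gene].to_numpy()
            for direction in ("gain", "loss"):
                event = gene_calls == direction
                table = np.array(
                    [
                        [(event & in_c).sum(), (event & ~in_c).sum()],
                        [(~event & in_c).sum(), (~event & ~in_c).sum()],
                    ]
                )
                chi2, p, fisher = _two_by_two_test(table)
                rows.append(
                    (
                        gene,
                        c,
                        direction,
                        event[in_c].mean(),
                        event[~in_c].mean(),
                        chi2,
                        p,
                        fisher,
                        p < alpha and event[in_c].mean() > event[~in_c].mean(),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cluster",
            "direction",
            "freq_in",
            "freq_rest",
            "chi2",
            "p",
            "fisher",
            "significant",
        ],
    )
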