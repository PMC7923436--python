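"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions:

* Beta matrices are TSV with the probe ID in the first column and one column
  per sample (the UCSC Xena dense-matrix dialect).
* Gene sets travel as GMT (name, description, genes, tab-separated).
* Somatic variants as MAF and copy-number segments as SEG are 1-based
  inclusive; the BED-like gene model is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
]

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix (first column = probe ID)."""
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    return beta


def write_beta_tsv(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    return annot


def write_annotation_tsv(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_probe_list(path: str | Path) -> list[str]:
    """One probe ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_expression_tsv(path: str | Path, min_median: float = 0.0) -> pd.DataFrame:
    """Read a genes x samples expression matrix, dropping genes whose median
    expression is <= ``min_median`` (low/absent genes are uninformative for
    rank-based enrichment)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    keep = expr.median(axis=1) > min_median
    return expr.loc[keep]


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_maf(path: str | Path) -> pd.DataFrame:
    maf = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    missing = [c for c in MAF_COLUMNS if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF is missing required columns: {missing}")
    return maf


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    maf.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in SEG_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"SEG is missing required columns: {missing}")
    return seg


def write_seg(seg: pd.DataFrame, path: str | Path) -> None:
    seg.to_csv(path, sep="\t", index=False)


def read_gene_model_bed(path: str | Path) -> pd.DataFrame:
    """BED-like gene model: chrom, start (0-based), end (half-open), gene."""
    model = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "gene"],
        dtype={"chromosome": str},
    )
    return model


def write_gene_model_bed(model: pd.DataFrame, path: str | Path) -> None:
    model[["chromosome", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_labels_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("cluster").to_csv(path, sep="\t", index_label="sample_id")
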