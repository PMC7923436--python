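"""Synthetic multi-omics cohort with known ground truth.

The generator emulates the data model of a TCGA-style renal tumor cohort:
a tumor and a normal methylation beta matrix with a planted set of
differentially methylated probes, a planted k-subtype pair-order structure on
those probes, an FPKM-like expression matrix positively coupled to a planted
per-sample immune-infiltration level, exponential survival with
subtype-specific hazards, a MAF with subtype-enriched mutated genes, and
copy-number segments with subtype-specific gains and losses. Every downstream
stage of the pipeline can therefore be tested against known truth without any
external download.

Beta values are drawn as clipped Gaussians around probe/subtype means: the
moments are then easy to control, at the cost of mild boundary distortion at
extreme means (documented, and avoided for planted probes by keeping their
means away from 0 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cpio

# the 28 immune infiltration cell types scored by ssGSEA
IMMUNE_CELL_TYPES = [
    "Activated_B_cell",
    "Activated_CD4_T_cell",
    "Activated_CD8_T_cell",
    "Activated_dendritic_cell",
    "CD56bright_natural_killer_cell",
    "CD56dim_natural_killer_cell",
    "Central_memory_CD4_T_cell",
    "Central_memory_CD8_T_cell",
    "Effector_memory_CD4_T_cell",
    "Effector_memory_CD8_T_cell",
    "Eosinophil",
    "Gamma_delta_T_cell",
    "Immature_B_cell",
    "Immature_dendritic_cell",
    "Macrophage",
    "Mast_cell",
    "MDSC",
    "Memory_B_cell",
    "Monocyte",
    "Natural_killer_T_cell",
    "Natural_killer_cell",
    "Neutrophil",
    "Plasmacytoid_dendritic_cell",
    "Regulatory_T_cell",
    "T_follicular_helper_cell",
    "Type_1_T_helper_cell",
    "Type_17_T_helper_cell",
    "Type_2_T_helper_cell",
]

CHECKPOINT_GENES = ["CD80", "CD86", "CD276", "CD274", "CTLA4", "PDCD1LG2", "PDCD1"]
HLA_GENES = ["HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DQA1"]

# renal clear-cell carcinoma driver genes used as the mutation pool
MUTATION_GENES = [
    "VHL", "PBRM1", "SETD2", "BAP1", "KDM5C", "MTOR", "TP53",
    "PTEN", "PIK3CA", "ARID1A", "TCEB1", "TSC1",
]

_GENES_PER_CELL_SET = 8
_N_IFN_GENES = 6
_N_APC_GENES = 6
_N_INFLAM_GENES = 8
_N_SIGNATURE_GENES = 25  # stromal and immune ESTIMATE-style signatures

_SUBTYPE_OFFSET = 0.12  # half-spread of per-subtype probe mean offsets
_MISSENSE_FRACTION = 0.85
_SILENT_RATE = 0.01


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Cohort sizes default to the training-cohort scale of a TCGA renal study
    (323 tumors, 160 normals). ``pair_signal`` is the fidelity with which a
    tumor sample's planted probes follow its subtype's mean template, on a
    [0.5, 1] scale where 0.5 means no subtype structure and 1 perfect
    adherence. Hazards are per-day event rates.
    """

    n_tumor: int = 323
    n_normal: int = 160
    n_subtypes: int = 3
    subtype_props: tuple[float, ...] | None = None
    n_probes: int = 1000
    n_dms_planted: int = 40
    delta_planted: float = 0.35
    pair_signal: float = 0.9
    noise_sd: float = 0.1
    missing_rate: float = 0.02
    n_genes: int = 2000
    hazard_by_subtype: tuple[float, ...] = (0.0008, 0.0004, 0.0016)
    censor_max_days: float = 2500.0
    mut_background: float = 0.05
    mut_enrichment: float = 10.0
    cnv_gain_value: float = 0.3
    cnv_loss_value: float = -0.3
    cnv_background_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_props is None:
            self.subtype_props = tuple(1.0 / self.n_subtypes for _ in range(self.n_subtypes))
        self.validate()

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("need at least two subtypes")
        for name in ("n_tumor", "n_normal", "n_probes", "n_dms_planted", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_dms_planted > self.n_probes:
            raise ValueError("cannot plant more DMS probes than probes")
        if abs(sum(self.subtype_props) - 1.0) > 1e-9:
            raise ValueError("subtype_props must sum to 1")
        if len(self.subtype_props) != self.n_subtypes:
            raise ValueError("subtype_props length must equal n_subtypes")
        if not 0.5 <= self.pair_signal <= 1.0:
            raise ValueError("pair_signal must lie in [0.5, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.delta_planted <= 1.0:
            raise ValueError("delta_planted must lie in [0, 1]")
        if len(self.hazard_by_subtype) != self.n_subtypes:
            raise ValueError("hazard_by_subtype length must equal n_subtypes")


@dataclass
class GroundTruth:
    """What the generator planted, for validating downstream inference."""

    sample_subtype: pd.Series  # tumor sample -> subtype in {1..k}
    planted_dms: list[str]
    planted_pairs: pd.DataFrame  # probe_a, probe_b, template_<s> columns
    immune_level: pd.Series  # tumor sample -> scalar in [0, 1]
    subtype_probe_means: pd.DataFrame = field(default_factory=pd.DataFrame)


def gene_universe(config: SimConfig) -> dict:
    """Deterministic gene naming shared by the expression and alteration
    generators: 28 disjoint immune-cell marker sets, auxiliary immune sets,
    stromal/immune signatures, checkpoints and a background pool."""
    sets: dict[str, list[str]] = {}
    counter = 0

    def fresh(n: int, prefix: str = "IG") -> list[str]:
        nonlocal counter
        out = [f"{prefix}{counter + i:04d}" for i in range(n)]
        counter += n
        return out

    for cell in IMMUNE_CELL_TYPES:
        sets[cell] = fresh(_GENES_PER_CELL_SET)
    sets["HLA"] = list(HLA_GENES)
    sets["Type_I_IFN_response"] = fresh(_N_IFN_GENES)
    sets["Type_II_IFN_response"] = fresh(_N_IFN_GENES)
    sets["APC_co_stimulation"] = fresh(_N_APC_GENES)
    sets["Inflammation_promoting"] = fresh(_N_INFLAM_GENES)
    sets["Checkpoint"] = list(CHECKPOINT_GENES)
    immune_members = sorted({g for s in sets.values() for g in s})
    sets["ImmuneSignature"] = fresh(_N_SIGNATURE_GENES)
    stromal = fresh(_N_SIGNATURE_GENES, prefix="SG")
    sets["StromalSignature"] = stromal
    immune_genes = sorted(
        set(immune_members) | set(sets["ImmuneSignature"])
    )
    named = sorted({g for s in sets.values() for g in s} | set(MUTATION_GENES))
    n_named = len(named)
    if config.n_genes < n_named:
        raise ValueError(
            f"n_genes={config.n_genes} smaller than the {n_named} genes required by the sets"
        )
    background = [f"BG{i:05d}" for i in range(config.n_genes - n_named)]
    return {
        "sets": sets,
        "immune_genes": immune_genes,
        "stromal_genes": stromal,
        "all_genes": named + background,
    }


def _subtype_severity(config: SimConfig) -> np.ndarray:
    """Rank subtypes by hazard onto [0, 1]; drives immune level and staging."""
    order = np.argsort(np.argsort(config.hazard_by_subtype))
    if config.n_subtypes == 1:
        return np.zeros(1)
    return order / (config.n_subtypes - 1)


def _draw_categories(rng, base: np.ndarray, severity: np.ndarray, strength: float = 1.2):
    """Sample one category per subject; higher-index categories become more
    likely with severity."""
    idx = np.arange(len(base))
    out = np.empty(len(severity), dtype=int)
    for i, sev in enumerate(severity):
        w = base * np.exp(strength * sev * idx)
        out[i] = rng.choice(len(base), p=w / w.sum())
    return out


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the methylation cohort.

    Returns (tumor beta matrix, normal beta matrix, probe annotation,
    clinical table, ground truth). Planted probes differ between tumor and
    normal by ``delta_planted`` in expectation; the remaining probes share
    identical means in both groups. Per-subtype mean offsets at planted
    probes create the pair-order structure, followed with fidelity
    ``pair_signal``. Missing values are injected into the tumor matrix at
    ``missing_rate``; the normal matrix stays complete.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    k = config.n_subtypes
    genes = gene_universe(config)

    probe_ids = [f"cg{i:08d}" for i in range(1, config.n_probes + 1)]
    tumor_ids = [f"TUMOR{i:04d}" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"NORMAL{i:04d}" for i in range(1, config.n_normal + 1)]

    # --- probe annotation -------------------------------------------------
    annot_genes = genes["immune_genes"]
    gene_meta = {}
    for gi, g in enumerate(genes["all_genes"]):
        gene_meta[g] = (
            f"chr{gi % 22 + 1}",
            1_000_000 + (gi // 22) * 200_000,  # TSS, 1-based
            "+" if gi % 2 == 0 else "-",
        )
    n_planted = config.n_dms_planted
    planted = probe_ids[:n_planted]
    rows = []
    n_sex = max(2, config.n_probes // 50)  # a few sex-chromosome probes
    for pi, probe in enumerate(probe_ids):
        g = annot_genes[pi % len(annot_genes)]
        chrom, tss, strand = gene_meta[g]
        in_window = pi < n_planted or rng.random() < 0.7
        if in_window:
            off = rng.integers(-1500, 400)
            position = tss + (off if strand == "+" else -off)
        else:
            position = tss + (6000 + int(rng.integers(0, 2000))) * (1 if strand == "+" else -1)
        if pi >= config.n_probes - n_sex:
            chrom = "chrX" if pi % 2 == 0 else "chrY"
        rows.append((probe, chrom, max(1, position), strand, g, tss))
    annotation = pd.DataFrame(
        rows, columns=["probe_id", "chromosome", "position", "strand", "gene", "tss"]
    )

    # --- subtype assignment ----------------------------------------------
    subtype = rng.choice(np.arange(1, k + 1), size=config.n_tumor, p=config.subtype_props)
    # guarantee every subtype occupied
    for s in range(1, k + 1):
        if not (subtype == s).any():
            subtype[rng.integers(config.n_tumor)] = s
    sample_subtype = pd.Series(subtype, index=tumor_ids, name="subtype")

    # --- probe means -------------------------------------------------------
    normal_mean = rng.uniform(0.05, 0.95, size=config.n_probes)
    shift_sign = rng.choice([-1.0, 1.0], size=n_planted)
    normal_mean[:n_planted] = np.where(
        shift_sign > 0,
        rng.uniform(0.20, 0.45, size=n_planted),
        rng.uniform(0.55, 0.80, size=n_planted),
    )
    tumor_base = normal_mean.copy()
    tumor_base[:n_planted] = normal_mean[:n_planted] + shift_sign * config.delta_planted

    # per-subtype offsets at planted probes, centered so E[tumor - normal]
    # stays at delta_planted
    offsets = np.zeros((n_planted, k))
    grid = np.linspace(-_SUBTYPE_OFFSET, _SUBTYPE_OFFSET, k)
    for j in range(n_planted):
        offsets[j] = rng.permutation(grid)
    subtype_means = tumor_base[:n_planted, None] + offsets  # planted x subtype
    subtype_probe_means = pd.DataFrame(
        subtype_means, index=planted, columns=[f"subtype_{s}" for s in range(1, k + 1)]
    )

    # --- tumor matrix -------------------------------------------------------
    q = 2.0 * config.pair_signal - 1.0  # probability of following own subtype
    tumor_vals = np.empty((config.n_probes, config.n_tumor))
    tumor_vals[n_planted:] = (
        tumor_base[n_planted:, None]
        + rng.normal(0.0, config.noise_sd, size=(config.n_probes - n_planted, config.n_tumor))
    )
    own = rng.random(size=(n_planted, config.n_tumor)) < q
    random_subtype = rng.integers(0, k, size=(n_planted, config.n_tumor))
    col_subtype = np.broadcast_to(subtype - 1, (n_planted, config.n_tumor))
    effective = np.where(own, col_subtype, random_subtype)
    tumor_vals[:n_planted] = (
        np.take_along_axis(subtype_means, effective, axis=1)
        + rng.normal(0.0, config.noise_sd, size=(n_planted, config.n_tumor))
    )
    tumor_vals = np.clip(tumor_vals, 0.0, 1.0)

    normal_vals = np.clip(
        normal_mean[:, None]
        + rng.normal(0.0, config.noise_sd, size=(config.n_probes, config.n_normal)),
        0.0,
        1.0,
    )

    if config.missing_rate > 0:
        mask = rng.random(size=tumor_vals.shape) < config.missing_rate
        # keep at least 30% of complete probes so KNN imputation has donors
        complete_quota = max(int(0.3 * config.n_probes), 1)
        mask[rng.permutation(config.n_probes)[:complete_quota]] = False
        tumor_vals = np.where(mask, np.nan, tumor_vals)

    tumor = pd.DataFrame(tumor_vals, index=probe_ids, columns=tumor_ids)
    normal = pd.DataFrame(normal_vals, index=probe_ids, columns=normal_ids)

    # --- pair templates -----------------------------------------------------
    from itertools import combinations

    pair_rows = []
    for a_i, b_i in combinations(range(n_planted), 2):
        a, b = planted[a_i], planted[b_i]
        row = {"probe_a": a, "probe_b": b}
        for s in range(1, k + 1):
            row[f"template_{s}"] = int(subtype_means[a_i, s - 1] > subtype_means[b_i, s - 1])
        pair_rows.append(row)
    planted_pairs = pd.DataFrame(pair_rows)

    # --- immune level: harsher subtypes are more infiltrated ----------------
    severity = _subtype_severity(config)
    level_mean = 0.2 + 0.6 * severity
    immune_level = pd.Series(
        np.clip(level_mean[subtype - 1] + rng.normal(0, 0.08, config.n_tumor), 0, 1),
        index=tumor_ids,
        name="immune_level",
    )

    # --- clinical table ------------------------------------------------------
    hazards = np.asarray(config.hazard_by_subtype)[subtype - 1]
    event_time = rng.exponential(1.0 / hazards)
    censor_time = rng.uniform(60.0, config.censor_max_days, size=config.n_tumor)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 31.0)  # cohort inclusion requires >30 days follow-up
    sev_per_sample = severity[subtype - 1]
    t_cat = _draw_categories(rng, np.array([0.45, 0.25, 0.2, 0.1]), sev_per_sample)
    n_cat = _draw_categories(rng, np.array([0.8, 0.2]), sev_per_sample)
    m_cat = _draw_categories(rng, np.array([0.8, 0.2]), sev_per_sample)
    g_cat = _draw_categories(rng, np.array([0.15, 0.4, 0.3, 0.15]), sev_per_sample)
    s_cat = _draw_categories(rng, np.array([0.4, 0.15, 0.25, 0.2]), sev_per_sample)
    clinical = pd.DataFrame(
        {
            "time": np.round(time, 1),
            "event": event,
            "T": [f"T{i + 1}" for i in t_cat],
            "N": [f"N{i}" for i in n_cat],
            "M": [f"M{i}" for i in m_cat],
            "grade": [f"G{i + 1}" for i in g_cat],
            "stage": [["I", "II", "III", "IV"][i] for i in s_cat],
            "age": np.round(rng.normal(61, 11, config.n_tumor)).clip(26, 90).astype(int),
            "sex": rng.choice(["male", "female"], size=config.n_tumor, p=[0.65, 0.35]),
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )

    truth = GroundTruth(
        sample_subtype=sample_subtype,
        planted_dms=list(planted),
        planted_pairs=planted_pairs,
        immune_level=immune_level,
        subtype_probe_means=subtype_probe_means,
    )
    return tumor, normal, annotation, clinical, truth


def generate_expression(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """FPKM-like expression coupled to the planted immune level.

    Genes belonging to immune gene sets increase with a sample's
    immune_level; stromal signature genes follow an independent per-sample
    stromal level; background genes are uncoupled. Returns the genes x
    samples matrix and the gene-set collection (28 cell-marker sets plus
    auxiliary, signature and checkpoint sets).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = gene_universe(config)
    all_genes = genes["all_genes"]
    samples = truth.immune_level.index
    n = len(samples)
    base = rng.lognormal(mean=1.0, sigma=0.8, size=(len(all_genes), 1))
    noise = rng.lognormal(mean=0.0, sigma=0.35, size=(len(all_genes), n))
    expr = base * noise
    immune_idx = np.isin(all_genes, genes["immune_genes"])
    stromal_idx = np.isin(all_genes, genes["stromal_genes"])
    immune_boost = np.exp(2.5 * (truth.immune_level.to_numpy() - 0.5))
    stromal_level = rng.uniform(0.0, 1.0, size=n)
    stromal_boost = np.exp(0.8 * (stromal_level - 0.5))
    expr[immune_idx] *= immune_boost[None, :]
    expr[stromal_idx] *= stromal_boost[None, :]
    matrix = pd.DataFrame(expr, index=all_genes, columns=samples)
    return matrix, dict(genes["sets"])


def generate_alterations(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Somatic mutations (MAF), copy-number segments (SEG) and the gene model.

    Two driver genes are mutated at ``mut_background * mut_enrichment`` in one
    subtype each (the first and the last) against ``mut_background``
    elsewhere; one gene gains (+``cnv_gain_value``) in subtype 1 and one loses
    in subtype 2. ``mut_enrichment=1`` reduces to a uniform null. MAF and SEG
    coordinates are 1-based inclusive; the gene model is 0-based half-open.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = gene_universe(config)
    k = config.n_subtypes
    subtype = truth.sample_subtype
    samples = subtype.index.tolist()

    model_genes = MUTATION_GENES + genes["immune_genes"][:40]
    chrom_len = 30_000_000
    rows = []
    for gi, g in enumerate(model_genes):
        chrom = f"chr{gi % 22 + 1}"
        start = 1_000_000 + (gi // 22) * 400_000  # 0-based half-open
        rows.append((g, chrom, start, start + 20_000))
    gene_model = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])

    # --- MAF ---------------------------------------------------------------
    enriched = {MUTATION_GENES[0]: 1, MUTATION_GENES[3]: k}  # gene -> subtype
    coords = gene_model.set_index("gene")
    maf_rows = []
    classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del"]
    for g in MUTATION_GENES:
        rate = np.full(len(samples), config.mut_background)
        if g in enriched:
            rate[(subtype == enriched[g]).to_numpy()] = min(
                0.95, config.mut_background * config.mut_enrichment
            )
        hit = rng.random(len(samples)) < rate
        silent = rng.random(len(samples)) < _SILENT_RATE
        for si, s in enumerate(samples):
            if hit[si] or silent[si]:
                pos = int(coords.loc[g, "start"]) + int(rng.integers(0, 20_000)) + 1
                if hit[si]:
                    vc = classes[int(rng.choice(3, p=[_MISSENSE_FRACTION, 0.1, 0.05]))]
                else:
                    vc = "Silent"
                maf_rows.append(
                    (g, coords.loc[g, "chromosome"], pos, pos, vc, s)
                )
    maf = pd.DataFrame(maf_rows, columns=cpio.MAF_COLUMNS)

    # --- SEG ----------------------------------------------------------------
    gain_gene, loss_gene = genes["immune_genes"][0], genes["immune_genes"][1]
    gain_idx = model_genes.index(gain_gene)
    loss_idx = model_genes.index(loss_gene)
    special = {
        coords.loc[gain_gene, "chromosome"]: ("gain", gain_idx),
        coords.loc[loss_gene, "chromosome"]: ("loss", loss_idx),
    }
    chroms = sorted(gene_model["chromosome"].unique(), key=lambda c: int(c[3:]))
    seg_rows = []
    # 1-based inclusive, non-overlapping, covering the chromosome
    bounds = [(1, 10_000_000), (10_000_001, 20_000_000), (20_000_001, chrom_len)]
    for s in samples:
        st = int(subtype.loc[s])
        for chrom in chroms:
            for b0, b1 in bounds:
                mean = float(rng.normal(0.0, config.cnv_background_sd))
                if chrom in special and b0 == 1:
                    kind, _ = special[chrom]
                    if kind == "gain" and st == 1:
                        mean = config.cnv_gain_value + float(
                            rng.normal(0.0, config.cnv_background_sd / 3)
                        )
                    elif kind == "loss" and st == min(2, k):
                        mean = config.cnv_loss_value + float(
                            rng.normal(0.0, config.cnv_background_sd / 3)
                        )
                seg_rows.append(
                    (s, chrom, b0, b1, (b1 - b0) // 5000, round(mean, 4))
                )
    seg = pd.DataFrame(seg_rows, columns=cpio.SEG_COLUMNS)
    return maf, seg, gene_model


def platform_shift(
    beta: pd.DataFrame,
    shift: float = 0.05,
    probes: list[str] | None = None,
) -> pd.DataFrame:
    """Emulate a second array platform.

    Optionally restricts to a probe subset (a 27K-like platform carries fewer
    probes) and applies the platform-wide monotone distortion
    ``(x + shift) / (1 + shift)``, which preserves [0, 1] and every
    within-sample ordering — exactly the kind of batch effect the pair scores
    are designed to ignore.
    """
    out = beta if probes is None else beta.loc[probes]
    return (out + shift) / (1.0 + shift)


def testing_probe_subset(
    config: SimConfig, truth: GroundTruth, keep_fraction: float = 0.3
) -> list[str]:
    """Probes retained on the reduced testing platform: all planted DMS
    probes plus a deterministic random subset of the rest."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    probe_ids = [f"cg{i:08d}" for i in range(1, config.n_probes + 1)]
    others = [p for p in probe_ids if p not in set(truth.planted_dms)]
    n_keep = int(round(keep_fraction * len(others)))
    kept = rng.choice(others, size=n_keep, replace=False).tolist()
    return sorted(set(truth.planted_dms) | set(kept))


def write_cohort(outdir: str | Path, config: SimConfig) -> GroundTruth:
    """Generate everything and write the plain-text artifact files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tumor, normal, annotation, clinical, truth = generate_cohort(config)
    expr, sets = generate_expression(config, truth)
    maf, seg, gene_model = generate_alterations(config, truth)
    cpio.write_beta_tsv(tumor, outdir / "beta_tumor.tsv")
    cpio.write_beta_tsv(normal, outdir / "beta_normal.tsv")
    cpio.write_annotation_tsv(annotation, outdir / "probe_annotation.tsv")
    cpio.write_clinical_tsv(clinical, outdir / "clinical.tsv")
    cpio.write_expression_tsv(expr, outdir / "expression.tsv")
    cpio.write_gmt(sets, outdir / "gene_sets.gmt")
    cpio.write_maf(maf, outdir / "mutations.maf")
    cpio.write_seg(seg, outdir / "segments.seg")
    cpio.write_gene_model_bed(gene_model, outdir / "gene_model.bed")
    cpio.write_labels_tsv(truth.sample_subtype, outdir / "true_subtypes.tsv")
    return truth
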