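"""Generate a synthetic multi-omics cohort with known subtype ground truth.

The generator plants: tumor-vs-normal methylation shifts at designated
probes, a 3-subtype pair-order structure on those probes, immune-coupled
expression, subtype-dependent survival, and subtype-enriched mutations and
copy-number events.
"""

import cpgpairs as cp

cfg = cp.SimConfig(
    n_tumor=120, n_normal=60, n_probes=300, n_dms_planted=40, n_genes=2000, seed=7
)
tumor, normal, annotation, clinical, truth = cp.generate_cohort(cfg)
expr, sets = cp.generate_expression(cfg, truth)
maf, seg, gene_model = cp.generate_alterations(cfg, truth)

print(f"tumor beta matrix : {tumor.shape[0]} probes x {tumor.shape[1]} samples")
print(f"normal beta matrix: {normal.shape[0]} probes x {normal.shape[1]} samples")
print(f"missing tumor entries: {int(tumor.isna().sum().sum())}")
print(f"planted DMS probes: {len(truth.planted_dms)}")
print(f"subtype sizes: {truth.sample_subtype.value_counts().sort_index().to_dict()}")
print(f"expression: {expr.shape[0]} genes x {expr.shape[1]} samples; {len(sets)} gene sets")
print(f"MAF records: {len(maf)}; segments: {len(seg)}; modeled genes: {len(gene_model)}")
# The planted truth (subtype labels, DMS list, pair templates, immune levels)
# is what every downstream example validates against.
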