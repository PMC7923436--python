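"""Score immune infiltration per sample with ssGSEA, derive ESTIMATE-style
tumor-microenvironment scores, and compare them across subtypes."""

import cpgpairs as cp
from cpgpairs.synthetic import IMMUNE_CELL_TYPES

cfg = cp.SimConfig(
    n_tumor=120, n_normal=60, n_probes=300, n_dms_planted=40, n_genes=2000, seed=7
)
_, _, _, _, truth = cp.generate_cohort(cfg)
expr, sets = cp.generate_expression(cfg, truth)
labels = truth.sample_subtype

cell_sets = {name: sets[name] for name in IMMUNE_CELL_TYPES}
scores = cp.ssgsea(expr, cell_sets, alpha=0.25)
table = cp.compare_sets_by_subtype(scores, labels)
n_sig = int((table["p_value"] < 0.05).sum())
print(f"immune cell types differing across subtypes (Kruskal-Wallis p<0.05): {n_sig}/28")

est = cp.estimate_scores(expr, sets["StromalSignature"], sets["ImmuneSignature"])
for col in ("stromal_score", "immune_score", "estimate_score", "tumor_purity"):
    med = est[col].groupby(labels).median()
    print(f"median {col} by subtype: {med.round(3).to_dict()}")
# The subtype with the highest planted infiltration shows the highest immune
# and ESTIMATE scores and the lowest tumor purity; stromal scores, which are
# planted independently of subtype, barely differ.

cpk = cp.checkpoint_expression(expr, labels)
print("checkpoint genes with subtype-dependent expression:")
print(cpk[cpk["p_value"] < 0.05].round(4))
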