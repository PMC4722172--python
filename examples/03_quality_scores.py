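"""The three dataset-quality scores: GO, codon and reproducibility.

All three grade a coexpression dataset without re-running the experiments:
the GO score asks whether low-MR pairs share GO biological-process terms
(partial ROC AUC at FPR <= 0.01, x 1E4); the codon score asks whether a
gene's coexpression list resembles its codon-usage-similarity list (median
COXSIM x 1E2, annotation-free); the reproducibility score asks whether
other datasets reproduce each guide's list, normalized by how adequate the
best reference is (median maxCOXSIM / bitscore ratio, x 1E1).
"""

from coexkit import go_score, reproducibility_score
from coexkit.fixtures import default_collection, gen_go, gen_sequences
from coexkit.scores import codon_mr_table, codon_score, codon_usage

collection, truth, cfg = default_collection(seed=17)
ds = collection.datasets["dsp1-x"]

annotations = gen_go(cfg, "dsp1")
print(f"GO score (1E-04 units): {go_score(ds.table, annotations):.2f}")

cds, _ = gen_sequences(cfg, "dsp1")
codon_table = codon_mr_table(
    [codon_usage(cds[g], gene=g) for g in ds.table.gene_ids]
)
aligned = [
    cfg.gene_name("dsp1", i)
    for m in truth.modules
    if m.name in truth.codon_aligned_modules and m.scope != "monocot"
    for i in m.gene_indices
]
print(f"codon score, all guides (1E-02 units): "
      f"{codon_score(ds.table, codon_table):.2f}")
print(f"codon score, codon-aligned module guides: "
      f"{codon_score(ds.table, codon_table, guides=aligned):.2f}")

module_guides = [
    cfg.gene_name("dsp1", i)
    for m in truth.modules if m.scope in ("conserved", "dicot")
    for i in m.gene_indices
]
score = reproducibility_score("dsp1-x", collection, guides=module_guides)
print(f"reproducibility score, module guides (1E-01 units): {score:.2f}")
print("(10.0 would mean every guide's list is perfectly reproduced by an "
      "equally-close reference)")
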