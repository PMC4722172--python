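"""Conserved vs lineage-specific coexpression of ortholog pairs.

For each planted module, every gene pair's coexpression strength is
averaged (geometric mean of MR) over the dicot-clade datasets and over the
monocot-clade datasets; the module is then classified from the medians:
strong in both clades = conserved, strong in one and absent in the other =
lineage-specific.
"""

import itertools

from coexkit import classify_module_lineage, geometric_avg_mr, scaled_lineage_thresholds
from coexkit.fixtures import default_collection

collection, truth, cfg = default_collection(seed=17)
strong, weak = scaled_lineage_thresholds(cfg.n_genes)
print(f"thresholds at n={cfg.n_genes}: strong MR < {strong}, weak MR > {weak}")

clade_ds = {
    clade: [d for d in collection.dataset_ids
            if cfg.clade_of(collection.species_of(d)) == clade]
    for clade, _ in cfg.clades
}


def clade_avg(pair, clade):
    tables = [collection.datasets[d].table for d in clade_ds[clade]]
    pairs = [
        (cfg.gene_name(collection.species_of(d), pair[0]),
         cfg.gene_name(collection.species_of(d), pair[1]))
        for d in clade_ds[clade]
    ]
    return geometric_avg_mr(pairs, tables)


for m in truth.modules:
    pair_avgs = [
        (clade_avg((a, b), "dicot"), clade_avg((a, b), "monocot"))
        for a, b in itertools.combinations(m.gene_indices, 2)
    ]
    label = classify_module_lineage(pair_avgs, strong, weak)
    d = sum(a for a, _ in pair_avgs) / len(pair_avgs)
    mo = sum(b for _, b in pair_avgs) / len(pair_avgs)
    print(f"{m.name} (planted {m.scope:9s}): dicot avg MR {d:7.1f}, "
          f"monocot avg MR {mo:7.1f} -> {label}")
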