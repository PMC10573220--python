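"""Generate a seeded synthetic two-condition RNA-seq dataset.

Writes the count matrix, design, reference regulon, PPI table, gene
sets and ground-truth sidecar, then prints what was planted.  The
planted structure (DE genes, co-expression blocks, a densely
interconnected TF core with PPI support) is what every downstream
stage tries to recover.
"""

import perionet as pn
from perionet import io

cfg = pn.SyntheticConfig(rng_seed=1)
regulon, truth = pn.generate_reference_regulon(cfg)
counts = pn.generate_counts(regulon, truth, cfg)
ppi = pn.generate_ppi(regulon, truth, cfg)
sets = pn.generate_gene_sets(truth, n_decoys=5, seed=1,
                             universe=sorted(regulon.graph.nodes()))
pn.validate_ground_truth(regulon, truth, cfg, counts)

paths = io.write_synthetic_dataset("example_data", regulon, truth,
                                   counts, ppi, sets)

print(f"reference regulon: {len(regulon.tfs)} TFs, "
      f"{regulon.graph.number_of_edges()} edges")
print(f"counts: {counts.counts.shape[0]} genes x "
      f"{counts.counts.shape[1]} samples "
      f"({cfg.n_replicates_per_condition} replicates per condition)")
print(f"planted: {len(truth.de_genes)} DE genes at |log2FC| = "
      f"{cfg.planted_lfc}, "
      f"{len(set(truth.module_labels.values()))} co-expression blocks, "
      f"{len(truth.mr_core)}-TF master-regulator core")
print(f"files written to: {paths['counts'].rsplit('/', 1)[0]}/")
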