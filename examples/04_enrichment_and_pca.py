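"""Pathway enrichment of a DEG set and PCA of the count matrix.

Builds on the DE scenario: the planted DEGs are assigned to a synthetic
"lipid metabolism" pathway, which should come out strongly enriched
(hypergeometric upper tail, significant at p < 0.005), while a random
pathway should not. PCA on log2 CPM of the most variant genes separates the
strains on PC1.
"""
import numpy as np

from crispant_audit import (
    default_design,
    hypergeometric_enrichment,
    nb_de_test,
    pca_top_variant,
    simulate_counts,
)

meta = default_design(n_per_group=6)
counts, meta, truth = simulate_counts(
    n_genes=2000, meta=meta, de_fraction=0.1, planted_log2fc=2.0, seed=42,
)
result = nb_de_test(counts, meta, ("WT", None), ("d6abc5_mt", None))
degs = set(result.index[result["is_deg"]])
universe = list(result.index)

rng = np.random.default_rng(0)
planted = list(truth.table.loc[truth.table["is_de"], "gene_id"])
pathways = {
    "lipid_metabolism_like": planted,
    "random_pathway": list(rng.choice(universe, size=len(planted), replace=False)),
}
enrichment = hypergeometric_enrichment(degs, pathways, universe)
print(enrichment.to_string(index=False))

pca = pca_top_variant(counts, top_n=1000)
print(f"\nPC1 explains {pca.varexp[0]:.1f}% of variance, "
      f"PC2 {pca.varexp[1]:.1f}%")
strain_of = {m.sample_id: m.strain for m in meta}
for strain in ("WT", "d6abc5_mt"):
    vals = [pca.scores.loc[s, "PC1"] for s in pca.scores.index
            if strain_of[s] == strain]
    print(f"  {strain:<10} PC1 range [{min(vals):8.2f}, {max(vals):8.2f}]")
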