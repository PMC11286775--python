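"""Differential expression in the three-state resistance model.

Simulates the parental / resistant / reversal count matrix, filters lowly
expressed genes, and runs the negative-binomial Wald contrast of resistant
over parental cells.
"""

from resistnet import SimConfig, filter_features, nb_contrast, simulate_omics

cfg = SimConfig(rng_seed=1)
counts, intensities, regulons, truth = simulate_omics(cfg)
counts = filter_features(counts)  # keep genes with >10 counts in >=20% of samples
res = nb_contrast(counts, pair=("parental", "resistant"))

degs = res.significant(fdr=0.10)
print(f"genes tested: {len(res.table)}; DEGs at FDR<10%: {len(degs)}")
top = res.table.dropna().reindex(res.table["qval"].sort_values().index).head(5)
print("\ntop 5 genes by q-value (log2FC is resistant over parental):")
print(top[["log2fc", "stat", "pval", "qval"]].round(4).to_string())
print(
    "\nA positive log2FC means the gene is induced in the resistant state; "
    "q is the Benjamini-Hochberg FDR."
)
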