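"""Plug an external tool's DEG table into the concordance machinery.

Real analyses use dedicated callers (edgeR, DESeq2, NOISeq, ...) run
outside this package. Their per-gene tables (gene_id, log2fc, pvalue,
padj) enter through the adapter and then behave exactly like built-in
methods in concordance matrices and consensus standards.
"""

import tempfile
from pathlib import Path

import pandas as pd

from refnof1 import (DEGSet, adapt_external, call_degs, concordance_matrix,
                     median_concordance, read_deg_table, significant_genes,
                     simulate)
from refnof1.simulate import SimConfig

counts, truth = simulate(SimConfig(seed=11, n_genes=500, n_replicates=7,
                                   baseline_log_mean=5.0,
                                   baseline_log_sd=1.0))

# stand-in for a table exported by an external tool: here, the planted
# truth with perfect adjusted p-values (a synthetic oracle table)
table = pd.DataFrame({
    "gene_id": counts.gene_ids,
    "log2fc": 0.0,
    "pvalue": [0.0001 if g in truth.deg_genes else 0.9
               for g in counts.gene_ids],
    "padj": [0.001 if g in truth.deg_genes else 0.95
             for g in counts.gene_ids],
})
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "oracle_tool.tsv"
    table.to_csv(path, sep="\t", index=False)
    external = read_deg_table(path, method_id="oracle_tool")

universe = list(counts.gene_ids)
sets = [adapt_external(external, universe, alpha=0.05, region_id="full")]
for method in ("nb_wald", "zlogfc"):
    genes = significant_genes(call_degs(method, counts))
    sets.append(DEGSet(method, "full", genes))

cm = concordance_matrix(sets)
print("pairwise Jaccard concordance:")
print(cm.values.round(3))
print(f"\nregion median: {median_concordance(cm):.3f}")
print("\nThe external table was thresholded on its own adjusted p-values")
print("(no re-adjustment) and restricted to the shared gene universe.")
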