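"""Simulate a replicated two-condition RNA-seq experiment with known truth.

The generator emulates an isogenic stimulus/control design: negative-binomial
counts, log-normal baselines, mild library-size variation, and a planted 10%
of genes carrying true fold changes spread over the standard windows.
"""

from refnof1 import SimConfig, simulate

config = SimConfig(seed=11, n_genes=2000, n_replicates=7,
                   baseline_log_mean=5.0, baseline_log_sd=1.0)
counts, truth = simulate(config)

print(f"count matrix: {len(counts.gene_ids)} genes x "
      f"{len(counts.sample_ids)} samples")
print(f"conditions: {counts.condition_labels}, "
      f"{len(counts.samples_in('A'))} replicates each")
print(f"planted DEGs: {len(truth.deg_genes)} "
      f"({100 * len(truth.deg_genes) / len(counts.gene_ids):.0f}% of genes)")
print(truth.table.loc[sorted(truth.deg_genes)[:5],
                      ["true_fc", "oriented_fc", "baseline"]].round(2))
print("\nEach row shows one planted gene: its true A/B fold change, the")
print("orientation-free effect size (>= 1), and its baseline expression.")
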