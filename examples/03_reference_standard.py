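"""Build leave-method-out consensus reference standards for one region.

The reference standard's positives are the genes several independent
methods agree on within the optimal filter region; the method that will
later be evaluated is excluded so its artefacts cannot leak in.
"""

import math

from refnof1 import SimConfig, simulate
from refnof1.evaluation import build_region_rs
from refnof1.filtering import FilterRegion
from refnof1.reference import rs_sizes

counts, truth = simulate(SimConfig(seed=11, n_genes=2000, n_replicates=7,
                                   baseline_log_mean=5.0,
                                   baseline_log_sd=1.0))
region = FilterRegion(expression_cutoff=30, fc_lower=1.5, fc_upper=math.inf)
methods = ["nb_wald", "zlogfc", "rank_sum"]

inter = build_region_rs(counts, methods, region, "intersection",
                        exclude="pooled_exact")
major = build_region_rs(counts, methods, region, "majority",
                        exclude="pooled_exact")

print(f"region: {region.region_id}; contributors: {inter.method_ids}; "
      f"held out: {inter.excluded_method}")
print(rs_sizes([inter, major]).to_string(index=False))

truth_in_universe = truth.deg_genes & inter.universe
overlap = len(inter.positives & truth_in_universe)
print(f"\nintersection positives that are truly differential: "
      f"{overlap}/{len(inter.positives)}")
print("The intersection rule is strict (all methods must agree) and so")
print("precise; majority vote trades some precision for a larger standard.")
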