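"""Score single-subject predictions against a consensus standard.

The replicated samples are split into 4 reference replicates per condition
(which build the standard) and 3 disjoint 1-vs-1 hold-out pairs (which
emulate a single subject measured once per condition). The prediction
method is excluded from the standard — a heteromorphic evaluation.
"""

import math

from refnof1 import SimConfig, evaluate_method, make_holdout, simulate
from refnof1.filtering import FilterRegion

counts, _ = simulate(SimConfig(seed=11, n_genes=2000, n_replicates=7,
                               baseline_log_mean=5.0, baseline_log_sd=1.0))
plan = make_holdout(counts, n_reference_per_condition=4, n_pairs=3, seed=3)
region = FilterRegion(expression_cutoff=30, fc_lower=1.5, fc_upper=math.inf)

report = evaluate_method(
    counts, plan,
    prediction_method="pooled_exact",
    rs_methods=["nb_wald", "zlogfc", "rank_sum"],
    region=region, rs_rule="majority",
)

print(f"reference samples: {dict(plan.reference)}")
print(f"hold-out pairs: {list(plan.pairs)}\n")
for pm in report.pairs:
    print(f"pair {pm.pair}: precision={pm.precision}, recall={pm.recall}, "
          f"{pm.predicted_positives} predicted, "
          f"{pm.reference_positives} reference positives")
print(f"\naverage precision: {report.average_precision}")
print(f"average recall:    {report.average_recall}")
print("\nPrecision is the share of the single-subject calls confirmed by")
print("the multi-method consensus; recall is the share of the consensus")
print("recovered from just one sample per condition.")
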