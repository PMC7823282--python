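"""Hold-out evaluation of single-subject DEG predictions.

The replicated dataset is split into non-overlapping reference samples
(which build the consensus reference standard) and prediction pairs (one
sample per condition, emulating a single subject measured once in each
condition). The prediction method is run on each 1-vs-1 pair, its calls are
filtered with the same region filters as the standard, and precision/recall
are averaged over the pairs. The prediction method must not have contributed
to the standard: evaluating a method against a consensus it helped build is
an isomorphic evaluation and is refused outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .callers import METHODS, call_degs, significant_genes
from .errors import BiasGuardError, CapabilityError, SizingError
from .filtering import (FilterRegion, expression_filter, fold_change,
                        summarize, window_members)
from .io import CountMatrix, EvaluationReport, PairMetrics, _mean_defined
from .optimizer import OptimizerConfig, iter_region_deg_sets
from .reference import ReferenceStandard, build_rs

logger = logging.getLogger(__name__)

#: fixed dispersion handed to mean-based callers on 1-vs-1 pairs, where no
#: replicate-based estimate exists (isogenic designs have low biological
#: variability; see the methods note)
DEFAULT_TWCR_DISPERSION = 0.05


@dataclass(frozen=True)
class HoldoutPlan:
    """Reference samples per condition plus disjoint 1-vs-1 prediction pairs."""

    reference: Mapping[str, tuple[str, ...]]
    pairs: tuple[tuple[str, str], ...]
    seed: int

    @property
    def reference_samples(self) -> list[str]:
        return [s for cond in sorted(self.reference) for s in
                self.reference[cond]]


def make_holdout(counts: CountMatrix, n_reference_per_condition: int,
                 n_pairs: int, seed: int) -> HoldoutPlan:
    """Randomly split samples into reference and prediction sets.

    Deterministic given the seed; the i-th prediction pair takes the i-th
    held-out sample of each condition.
    """
    rng = np.random.default_rng(seed)
    a, b = counts.condition_labels
    reference: dict[str, tuple[str, ...]] = {}
    held: dict[str, list[str]] = {}
    for cond in (a, b):
        samples = sorted(counts.samples_in(cond))
        need = n_reference_per_condition + n_pairs
        if need > len(samples):
            raise SizingError(
                f"condition {cond!r} has {len(samples)} samples; "
                f"{n_reference_per_condition} reference + {n_pairs} pairs "
                f"need {need}"
            )
        order = rng.permutation(len(samples))
        shuffled = [samples[i] for i in order]
        reference[cond] = tuple(sorted(shuffled[:n_reference_per_condition]))
        held[cond] = shuffled[n_reference_per_condition:
                              n_reference_per_condition + n_pairs]
    pairs = tuple(zip(held[a], held[b]))
    return HoldoutPlan(reference=reference, pairs=pairs, seed=seed)


@dataclass(frozen=True)
class Metrics:
    """Precision/recall counts; None marks an undefined metric."""

    precision: float | None
    recall: float | None
    true_positives: int
    predicted_positives: int
    reference_positives: int
    universe_size: int


def precision_recall(predicted: Iterable[str],
                     rs: ReferenceStandard) -> Metrics:
    """Score a predicted gene set against a reference standard.

    Predictions outside the RS universe are dropped (logged). Precision is
    undefined with no predictions; recall is undefined with no positives.
    """
    predicted = set(predicted)
    outside = predicted - rs.universe
    if outside:
        logger.info("precision_recall: dropped %d predictions outside the "
                    "RS universe", len(outside))
    predicted &= rs.universe
    tp = len(predicted & rs.positives)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(rs.positives) if rs.positives else None
    return Metrics(precision=precision, recall=recall, true_positives=tp,
                   predicted_positives=len(predicted),
                   reference_positives=len(rs.positives),
                   universe_size=len(rs.universe))


def build_region_rs(counts: CountMatrix, methods: Sequence[str],
                    region: FilterRegion, rule: str,
                    exclude: str | None = None,
                    config: OptimizerConfig | None = None
                    ) -> ReferenceStandard:
    """Build the consensus RS of one grid region from replicated samples.

    The RS universe is the region's expression-filtered gene set; the
    fold-change window restricts the positives (each method's significant
    calls are stratified into the window before the consensus is taken).
    """
    config = config or OptimizerConfig()
    config = OptimizerConfig(
        cutoffs=(region.expression_cutoff,),
        fc_windows=((region.fc_lower, region.fc_upper),),
        target=config.target, alpha=config.alpha, scaling=config.scaling,
        pseudocount=config.pseudocount,
        retest_within_window=config.retest_within_window,
        caller_params=config.caller_params,
    )
    contributing = [m for m in methods if m != exclude]
    (_, deg_sets), = iter_region_deg_sets(counts, contributing, config)
    universe = expression_filter(counts, region.expression_cutoff)
    return build_rs(deg_sets, rule=rule, universe=universe, exclude=exclude,
                    region=region)


def _predict_pair(counts: CountMatrix, pair: tuple[str, str], method: str,
                  region: FilterRegion | None, alpha: float,
                  scaling: str, pseudocount: float,
                  twcr_dispersion: float) -> frozenset[str]:
    """Significant genes called by ``method`` on one 1-vs-1 sample pair."""
    spec = METHODS[method]
    if not spec.twcr_capable:
        raise CapabilityError(
            f"method {method!r} requires replicates and cannot be used on "
            "a 1-vs-1 prediction pair"
        )
    pair_matrix = counts.subset_samples(list(pair))
    params = {}
    if spec.needs_dispersion_for_twcr:
        params["dispersion"] = twcr_dispersion
    if region is None:
        result = call_degs(method, pair_matrix, alpha, **params)
        return significant_genes(result)
    universe = expression_filter(pair_matrix, region.expression_cutoff)
    sub = pair_matrix.subset_genes(universe)
    if len(universe) == 0:
        return frozenset()
    result = call_degs(method, sub, alpha, **params)
    fc = fold_change(summarize(sub, scaling), pseudocount)
    members = window_members(fc, (region.fc_lower, region.fc_upper))
    return significant_genes(result) & set(members)


def evaluate_method(counts: CountMatrix, plan: HoldoutPlan,
                    prediction_method: str, rs_methods: Sequence[str],
                    region: FilterRegion, rs_rule: str = "intersection",
                    alpha: float = 0.05,
                    filter_predictions: bool = True,
                    scaling: str = "total_count", pseudocount: float = 0.5,
                    twcr_dispersion: float = DEFAULT_TWCR_DISPERSION,
                    caller_params: Mapping[str, Mapping] | None = None,
                    ) -> EvaluationReport:
    """Score ``prediction_method`` on each hold-out pair against a consensus
    RS built once from the reference samples; average the defined metrics.

    ``prediction_method`` must not appear among ``rs_methods`` — scoring a
    method against a standard it contributed to is refused (bias guard).
    With ``filter_predictions`` the pair's calls pass through the same
    expression cutoff and fold-change window as the RS region; without it
    the full unfiltered pair calls are scored.
    """
    if prediction_method in rs_methods:
        raise BiasGuardError(
            f"prediction method {prediction_method!r} contributes to the "
            "reference standard (isomorphic evaluation)"
        )
    ref_matrix = counts.subset_samples(plan.reference_samples)
    opt_config = OptimizerConfig(alpha=alpha, scaling=scaling,
                                 pseudocount=pseudocount,
                                 caller_params=caller_params or {})
    rs = build_region_rs(ref_matrix, rs_methods, region, rs_rule,
                         exclude=prediction_method, config=opt_config)
    pair_metrics = []
    for pair in plan.pairs:
        predicted = _predict_pair(
            counts, pair, prediction_method,
            region if filter_predictions else None,
            alpha, scaling, pseudocount, twcr_dispersion,
        )
        m = precision_recall(predicted, rs)
        pair_metrics.append(PairMetrics(
            pair=pair, precision=m.precision, recall=m.recall,
            true_positives=m.true_positives,
            predicted_positives=m.predicted_positives,
            reference_positives=m.reference_positives,
            universe_size=m.universe_size,
        ))
    provenance = {
        "rs_rule": rs_rule,
        "rs_methods": sorted(rs_methods),
        "excluded_method": prediction_method,
        "prediction_method": prediction_method,
        "region": region.region_id,
        "seed": plan.seed,
        "alpha": alpha,
        "filter_predictions": filter_predictions,
        "twcr_dispersion": twcr_dispersion,
        "n_undefined_precision": sum(p.precision is None for p in pair_metrics),
        "n_undefined_recall": sum(p.recall is None for p in pair_metrics),
    }
    return EvaluationReport(
        pairs=tuple(pair_metrics),
        average_precision=_mean_defined([p.precision for p in pair_metrics]),
        average_recall=_mean_defined([p.recall for p in pair_metrics]),
        provenance=provenance,
    )
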