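"""Grid search for the filter combination attaining a target concordance.

The search walks the (expression cutoff, fold-change window) grid — cutoffs
ascending in the outer loop, windows ascending by lower bound in the inner
loop — so the first combination whose region median Jaccard reaches the
target is also the least destructive one (smallest thresholds, most data
preserved). DEG calling runs once per expression cutoff on the full filtered
universe; the fold-change windows then stratify the significant sets rather
than triggering re-testing (a ``retest_within_window`` flag provides the
alternative behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import pandas as pd

from . import callers as _callers
from .callers import DEGSet, call_degs, significant_genes
from .concordance import ConcordanceMatrix, concordance_matrix, \
    median_concordance
from .errors import ConfigurationError
from .filtering import (DEFAULT_EXPRESSION_CUTOFFS, DEFAULT_FC_WINDOWS,
                        FilterRegion, _check_windows, expression_filter,
                        fold_change, summarize, window_members)
from .io import CountMatrix


@dataclass(frozen=True)
class OptimizerConfig:
    """Grid definition plus the calling/normalisation settings it needs."""

    cutoffs: tuple[float, ...] = DEFAULT_EXPRESSION_CUTOFFS
    fc_windows: tuple[tuple[float, float], ...] = DEFAULT_FC_WINDOWS
    target: float = 0.75
    alpha: float = _callers.DEFAULT_ALPHA
    scaling: str = "total_count"
    pseudocount: float = 0.5
    retest_within_window: bool = False
    caller_params: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.cutoffs) != sorted(set(self.cutoffs)):
            raise ConfigurationError("cutoffs must be strictly ascending")
        _check_windows(self.fc_windows)
        if sorted(self.fc_windows) != list(self.fc_windows):
            raise ConfigurationError("windows must ascend by lower bound")
        # targets above 1 are legal and simply unattainable (Jaccard <= 1)
        if self.target <= 0:
            raise ConfigurationError("target must be > 0")


@dataclass(frozen=True)
class OptimizerResult:
    attained: bool
    region: FilterRegion | None
    achieved_median: float | None
    #: (region, median) for every cell evaluated before stopping
    evaluated: tuple[tuple[FilterRegion, float | None], ...]

    @property
    def message(self) -> str:
        if self.attained:
            return (f"target attained at {self.region.region_id} "
                    f"(median Jaccard {self.achieved_median:.3f})")
        return "No threshold achieved target Jaccard Index"


def iter_region_deg_sets(counts: CountMatrix, methods: Sequence[str],
                         config: OptimizerConfig
                         ) -> Iterator[tuple[FilterRegion, list[DEGSet]]]:
    """Yield (region, per-method DEG sets) over the grid in traversal order."""
    if len(methods) < 2:
        raise ConfigurationError("need >= 2 methods")
    for cutoff in config.cutoffs:
        universe = expression_filter(counts, cutoff)
        sub = counts.subset_genes(universe)
        if len(universe) > 0:
            fc = fold_change(summarize(sub, config.scaling), config.pseudocount)
            results = None
            if not config.retest_within_window:
                results = {
                    m: call_degs(m, sub, config.alpha,
                                 **config.caller_params.get(m, {}))
                    for m in methods
                }
        for lo, hi in config.fc_windows:
            region = FilterRegion(cutoff, lo, hi)
            if len(universe) == 0:
                yield region, [DEGSet(m, region.region_id, frozenset())
                               for m in methods]
                continue
            members = set(window_members(fc, (lo, hi)))
            if config.retest_within_window:
                deg_sets = []
                for m in methods:
                    if members:
                        res = call_degs(m, sub.subset_genes(members),
                                        config.alpha,
                                        **config.caller_params.get(m, {}))
                        genes = significant_genes(res)
                    else:
                        genes = frozenset()
                    deg_sets.append(DEGSet(m, region.region_id, genes))
            else:
                deg_sets = [
                    DEGSet(m, region.region_id,
                           significant_genes(results[m]) & members)
                    for m in methods
                ]
            yield region, deg_sets


def optimize(counts: CountMatrix, methods: Sequence[str],
             config: OptimizerConfig) -> OptimizerResult:
    """Early-stopping grid search: return the first region whose defined
    median pairwise Jaccard reaches the target, or ``attained=False``.

    Deterministic: identical inputs yield identical results. An undefined
    median (all method pairs empty) never satisfies the target.
    """
    evaluated: list[tuple[FilterRegion, float | None]] = []
    for region, deg_sets in iter_region_deg_sets(counts, methods, config):
        med = median_concordance(concordance_matrix(deg_sets))
        evaluated.append((region, med))
        if med is not None and med >= config.target:
            return OptimizerResult(attained=True, region=region,
                                   achieved_median=med,
                                   evaluated=tuple(evaluated))
    return OptimizerResult(attained=False, region=None, achieved_median=None,
                           evaluated=tuple(evaluated))


def grid_medians(counts: CountMatrix, methods: Sequence[str],
                 config: OptimizerConfig
                 ) -> dict[FilterRegion, ConcordanceMatrix]:
    """Evaluate every grid cell regardless of target (powers the heatmaps)."""
    return {region: concordance_matrix(deg_sets)
            for region, deg_sets
            in iter_region_deg_sets(counts, methods, config)}


def medians_frame(grid: Mapping[FilterRegion, ConcordanceMatrix]
                  ) -> pd.DataFrame:
    """Cutoff x window table of region medians (NaN = undefined)."""
    records = {}
    for region, cm in grid.items():
        med = median_concordance(cm)
        records.setdefault(region.expression_cutoff, {})[
            (region.fc_lower, region.fc_upper)] = med
    frame = pd.DataFrame(records).T.sort_index()
    frame.index.name = "cutoff"
    return frame[sorted(frame.columns)]
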