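"""Per-gene expression summaries, fold changes, and grid-region filters.

The fold change of gene *k* is the ratio A_k/B_k of its (optionally
library-size scaled) mean expression between the two conditions. Up- and
down-regulation are not distinguished when filtering: a down-regulated gene
(FC < 1) is mapped to its reciprocal, so every fold-change window lives on the
oriented scale [1, inf) and is symmetric about 1 in raw-ratio terms.

A grid region couples one low-expression cutoff with one fold-change window.
The expression cutoff is applied to the average *raw* count across all samples
(both conditions pooled) and defines the testing universe; the window then
stratifies genes within that universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix

logger = logging.getLogger(__name__)

#: Default fold-change windows (oriented scale, half-open [lower, upper)).
DEFAULT_FC_WINDOWS: tuple[tuple[float, float], ...] = (
    (1.0, 1.1), (1.1, 1.2), (1.2, 1.3), (1.3, 1.5), (1.5, math.inf),
)

#: Default low-expression cutoffs (mean raw count across all samples).
DEFAULT_EXPRESSION_CUTOFFS: tuple[float, ...] = (0, 5, 10, 20, 30, 50)


@dataclass(frozen=True)
class FilterRegion:
    """One grid cell: an expression cutoff plus an oriented FC window."""

    expression_cutoff: float
    fc_lower: float
    fc_upper: float

    def __post_init__(self) -> None:
        if self.expression_cutoff < 0:
            raise ConfigurationError("expression cutoff must be >= 0")
        if not (1.0 <= self.fc_lower < self.fc_upper):
            raise ConfigurationError(
                f"need 1 <= fc_lower < fc_upper, got "
                f"[{self.fc_lower}, {self.fc_upper})"
            )

    @property
    def region_id(self) -> str:
        upper = "inf" if math.isinf(self.fc_upper) else f"{self.fc_upper:g}"
        return f"cutoff={self.expression_cutoff:g},fc=[{self.fc_lower:g},{upper})"

    def contains(self, oriented_fc: float) -> bool:
        return self.fc_lower <= oriented_fc < self.fc_upper


def build_grid(cutoffs: Sequence[float] = DEFAULT_EXPRESSION_CUTOFFS,
               fc_windows: Sequence[tuple[float, float]] = DEFAULT_FC_WINDOWS,
               ) -> list[FilterRegion]:
    """All (cutoff, window) regions, cutoffs ascending outer, windows inner."""
    _check_windows(fc_windows)
    if list(cutoffs) != sorted(set(cutoffs)):
        raise ConfigurationError("cutoffs must be strictly ascending")
    return [FilterRegion(c, lo, hi) for c in cutoffs for lo, hi in fc_windows]


def _check_windows(windows: Iterable[tuple[float, float]]) -> None:
    ordered = sorted(windows)
    for (lo1, hi1), (lo2, _) in zip(ordered, ordered[1:]):
        if lo2 < hi1:
            raise ConfigurationError(
                f"overlapping fold-change windows [{lo1},{hi1}) and [{lo2},...)"
            )


@dataclass(frozen=True)
class ConditionSummary:
    """Per-gene condition means.

    ``mean_a``/``mean_b`` are arithmetic means of (optionally scaled) counts
    over each condition's samples and feed the fold change; ``overall_mean``
    is always the mean of *raw* counts over all samples and feeds only the
    low-expression cutoff.
    """

    mean_a: pd.Series
    mean_b: pd.Series
    overall_mean: pd.Series
    condition_labels: tuple[str, str]
    scaling: str


def summarize(counts: CountMatrix, scaling: str = "total_count"
              ) -> ConditionSummary:
    """Compute per-gene means for both conditions and overall.

    ``scaling="total_count"`` rescales each sample to the mean library size
    before averaging (a sample with zero total is left unscaled);
    ``scaling="none"`` averages raw counts.
    """
    if scaling not in ("none", "total_count"):
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    a, b = counts.condition_labels
    raw = counts.counts.astype(float)
    if scaling == "total_count":
        lib = raw.sum(axis=0)
        factors = lib / lib.mean() if lib.mean() > 0 else lib * 0 + 1.0
        factors = factors.replace(0.0, 1.0)
        scaled = raw / factors
    else:
        scaled = raw
    return ConditionSummary(
        mean_a=scaled[counts.samples_in(a)].mean(axis=1),
        mean_b=scaled[counts.samples_in(b)].mean(axis=1),
        overall_mean=raw.mean(axis=1),
        condition_labels=(a, b),
        scaling=scaling,
    )


def fold_change(summary: ConditionSummary, pseudocount: float = 0.5
                ) -> pd.DataFrame:
    """Per-gene fold change A_k/B_k with reciprocal orientation.

    The pseudocount is added to *both* means only when either is zero (and
    the pseudocount is positive), minimally perturbing the ratio; a gene with
    both means zero and pseudocount 0 has no defined fold change and is
    excluded from every window.

    Returns a frame indexed by gene with columns ``fc``, ``oriented_fc``
    (= max(fc, 1/fc) >= 1), ``direction`` ("up" if fc >= 1 else "down") and
    ``defined`` (bool).
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    a = summary.mean_a.to_numpy(dtype=float)
    b = summary.mean_b.to_numpy(dtype=float)
    any_zero = (a == 0) | (b == 0)
    if pseudocount > 0:
        num = np.where(any_zero, a + pseudocount, a)
        den = np.where(any_zero, b + pseudocount, b)
    else:
        num, den = a, b
    defined = ~((num == 0) & (den == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(defined, np.divide(num, den,
                                         out=np.full_like(num, np.nan),
                                         where=den != 0), np.nan)
        fc = np.where(defined & (den == 0), np.inf, fc)
        oriented = np.where(fc >= 1, fc, np.divide(1.0, fc,
                                                   out=np.full_like(fc, np.inf),
                                                   where=fc != 0))
    oriented = np.where(defined, oriented, np.nan)
    direction = np.where(fc >= 1, "up", "down")
    return pd.DataFrame(
        {"fc": fc, "oriented_fc": oriented,
         "direction": np.where(defined, direction, "undefined"),
         "defined": defined},
        index=summary.mean_a.index,
    )


def expression_filter(counts: CountMatrix, cutoff: float) -> pd.Index:
    """Genes whose mean raw count across all samples is >= ``cutoff``.

    An empty result is valid; the number of removed genes is logged.
    """
    overall = counts.counts.mean(axis=1)
    keep = overall.index[overall.to_numpy() >= cutoff]
    removed = len(overall) - len(keep)
    if removed:
        logger.info("expression_filter(cutoff=%g): removed %d of %d genes",
                    cutoff, removed, len(overall))
    return keep


def assign_window(oriented_fc: float,
                  regions: Sequence[FilterRegion]) -> FilterRegion | None:
    """The unique region whose half-open window contains ``oriented_fc``.

    The regions must share an expression cutoff and be non-overlapping.
    Returns None when no window matches or the fold change is undefined.
    """
    if len({r.expression_cutoff for r in regions}) > 1:
        raise ConfigurationError("regions must share one expression cutoff")
    _check_windows([(r.fc_lower, r.fc_upper) for r in regions])
    if oriented_fc is None or np.isnan(oriented_fc):
        return None
    for region in regions:
        if region.contains(oriented_fc):
            return region
    return None


def window_members(fc_frame: pd.DataFrame, window: tuple[float, float]
                   ) -> pd.Index:
    """Genes whose defined oriented fold change falls in [lower, upper)."""
    lo, hi = window
    orient = fc_frame["oriented_fc"].to_numpy(dtype=float)
    mask = fc_frame["defined"].to_numpy() & (orient >= lo) & (orient < hi)
    return fc_frame.index[mask]
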