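"""Pairwise Jaccard concordance between per-method DEG sets.

The Jaccard index |M∩N|/|M∪N| measures how far two methods' significant-gene
lists agree within one grid region. A pair where both sets are empty carries
no information (no predictions were made) and is undefined; a pair with one
empty and one non-empty set scores 0. The region is summarised by the median
over the defined unordered pair values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .callers import DEGSet
from .errors import ConfigurationError


def jaccard(m: Iterable[str], n: Iterable[str]) -> float | None:
    """|M∩N|/|M∪N|, or None (undefined) when both sets are empty."""
    m, n = set(m), set(n)
    union = m | n
    if not union:
        return None
    return len(m & n) / len(union)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Symmetric pairwise Jaccard values for one region (NaN = undefined)."""

    region_id: str
    method_ids: tuple[str, ...]
    values: pd.DataFrame  # methods x methods, NaN where undefined

    @property
    def pair_values(self) -> dict[tuple[str, str], float | None]:
        """Each unordered off-diagonal pair once, None for undefined."""
        out = {}
        for a, b in combinations(self.method_ids, 2):
            v = self.values.loc[a, b]
            out[(a, b)] = None if pd.isna(v) else float(v)
        return out

    @property
    def per_method_median(self) -> dict[str, float | None]:
        """Median concordance of each method with all others (diagnostic)."""
        out = {}
        for m in self.method_ids:
            vals = [self.values.loc[m, o] for o in self.method_ids if o != m]
            vals = [v for v in vals if not pd.isna(v)]
            out[m] = float(np.median(vals)) if vals else None
        return out


def concordance_matrix(deg_sets: Sequence[DEGSet]) -> ConcordanceMatrix:
    """All C(k,2) pairwise Jaccard values among k >= 2 methods, mirrored.

    The diagonal is 1 for methods with non-empty sets and undefined for
    empty ones (a method that predicted nothing cannot agree with itself).
    """
    if len(deg_sets) < 2:
        raise ConfigurationError("concordance needs >= 2 methods")
    ids = [d.method_id for d in deg_sets]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate method ids: {ids}")
    regions = {d.region_id for d in deg_sets}
    if len(regions) > 1:
        raise ConfigurationError(
            f"DEG sets span multiple regions: {sorted(regions)}"
        )
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for d in deg_sets:
        if d.genes:
            mat.loc[d.method_id, d.method_id] = 1.0
    for da, db in combinations(deg_sets, 2):
        v = jaccard(da.genes, db.genes)
        val = np.nan if v is None else v
        mat.loc[da.method_id, db.method_id] = val
        mat.loc[db.method_id, da.method_id] = val
    return ConcordanceMatrix(region_id=regions.pop(), method_ids=tuple(ids),
                             values=mat)


def median_concordance(matrix: ConcordanceMatrix) -> float | None:
    """Median over defined unordered pair values; None if all undefined."""
    vals = [v for v in matrix.pair_values.values() if v is not None]
    return float(np.median(vals)) if vals else None


def grid_long_frame(grid: Mapping[object, ConcordanceMatrix]) -> pd.DataFrame:
    """Long-format table of the full grid for TSV export and heatmaps.

    One row per (cutoff, window, method pair); undefined pairs have an
    empty jaccard field.
    """
    rows = []
    for region, cm in grid.items():
        for (ma, mb), v in cm.pair_values.items():
            rows.append({
                "cutoff": region.expression_cutoff,
                "fc_lower": region.fc_lower,
                "fc_upper": region.fc_upper,
                "method_a": ma,
                "method_b": mb,
                "jaccard": np.nan if v is None else v,
            })
    return pd.DataFrame(rows)
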