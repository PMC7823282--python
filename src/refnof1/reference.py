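"""Consensus reference standards from per-method DEG sets.

A reference standard (RS) is a computationally derived stand-in for a
biological gold standard: a consensus set of positives drawn from several
analytical methods' significant-gene lists, with the method under evaluation
excluded so its systematic artefacts cannot be replicated into the standard.
Negatives are the remaining genes of the region's filtered universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Sequence

import pandas as pd

from .callers import DEGSet
from .errors import ConfigurationError
from .filtering import FilterRegion

RULES = ("intersection", "majority")


@dataclass(frozen=True)
class ReferenceStandard:
    """Consensus positive set plus the universe it was drawn from."""

    rule: str
    method_ids: tuple[str, ...]
    excluded_method: str | None
    positives: FrozenSet[str]
    universe: FrozenSet[str]
    region: FilterRegion | None = None

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise ConfigurationError("RS positives must lie in the universe")
        if self.excluded_method in self.method_ids:
            raise ConfigurationError(
                f"excluded method {self.excluded_method!r} among contributors"
            )

    @property
    def negatives(self) -> FrozenSet[str]:
        return self.universe - self.positives


def build_rs(deg_sets: Sequence[DEGSet], rule: str,
             universe: Sequence[str],
             exclude: str | None = None,
             region: FilterRegion | None = None) -> ReferenceStandard:
    """Consensus of the contributing methods' significant sets.

    ``intersection`` keeps genes present in every contributing set;
    ``majority`` keeps genes present in strictly more than half of them
    (3-of-4 when four methods contribute). Positives are intersected with
    the universe. Excluding the evaluated method must leave >= 2 methods.
    """
    if rule not in RULES:
        raise ConfigurationError(f"unknown RS rule {rule!r}; use {RULES}")
    contributing = [d for d in deg_sets if d.method_id != exclude]
    if len(contributing) < 2:
        raise ConfigurationError(
            f"need >= 2 contributing methods after excluding {exclude!r}, "
            f"got {len(contributing)}"
        )
    universe_set = frozenset(universe)
    sets = [set(d.genes) for d in contributing]
    if rule == "intersection":
        positives = set.intersection(*sets)
    else:
        counts: dict[str, int] = {}
        for s in sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        positives = {g for g, c in counts.items() if c > len(sets) / 2}
    return ReferenceStandard(
        rule=rule,
        method_ids=tuple(sorted(d.method_id for d in contributing)),
        excluded_method=exclude,
        positives=frozenset(positives) & universe_set,
        universe=universe_set,
        region=region,
    )


def combine_reference_standards(parts: Sequence[ReferenceStandard]
                                ) -> ReferenceStandard:
    """Union of several regions' standards into one composite RS.

    Supports compositions like "the DEGs found at (cutoff 0, FC 1.3–1.5)
    united with those at (cutoff 30, FC > 1.5)": positives and universes
    are united; contributing methods must agree across parts.
    """
    if not parts:
        raise ConfigurationError("need >= 1 part")
    methods = {p.method_ids for p in parts}
    if len(methods) > 1:
        raise ConfigurationError("parts built from different method sets")
    excluded = {p.excluded_method for p in parts}
    if len(excluded) > 1:
        raise ConfigurationError("parts exclude different methods")
    positives = frozenset().union(*(p.positives for p in parts))
    universe = frozenset().union(*(p.universe for p in parts))
    rules = sorted({p.rule for p in parts})
    return ReferenceStandard(
        rule="+".join(rules),
        method_ids=parts[0].method_ids,
        excluded_method=parts[0].excluded_method,
        positives=positives,
        universe=universe,
        region=None,
    )


def rs_sizes(variants: Sequence[ReferenceStandard]) -> pd.DataFrame:
    """Positive/negative counts per RS variant (shared universe required)."""
    if len({v.universe for v in variants}) > 1:
        raise ConfigurationError("variants must share a universe")
    rows = [{"rule": v.rule,
             "excluded_method": v.excluded_method,
             "positives": len(v.positives),
             "negatives": len(v.negatives),
             "universe": len(v.universe)} for v in variants]
    return pd.DataFrame(rows)


def write_rs(rs: ReferenceStandard, path: str | Path,
             provenance_path: str | Path | None = None) -> None:
    """Export gene_id/label TSV plus a JSON provenance sidecar."""
    genes = sorted(rs.universe)
    labels = [1 if g in rs.positives else 0 for g in genes]
    pd.DataFrame({"gene_id": genes, "label": labels}
                 ).to_csv(path, sep="\t", index=False)
    if provenance_path is None:
        provenance_path = str(path) + ".provenance.json"
    doc = {
        "rule": rs.rule,
        "method_ids": list(rs.method_ids),
        "excluded_method": rs.excluded_method,
        "region": None if rs.region is None else {
            "expression_cutoff": rs.region.expression_cutoff,
            "fc_lower": rs.region.fc_lower,
            "fc_upper": ("inf" if rs.region.fc_upper == float("inf")
                         else rs.region.fc_upper),
        },
        "n_positives": len(rs.positives),
        "n_negatives": len(rs.negatives),
        "n_universe": len(rs.universe),
    }
    Path(provenance_path).write_text(json.dumps(doc, indent=2) + "\n")


def read_rs(path: str | Path,
            provenance_path: str | Path | None = None) -> ReferenceStandard:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    universe = frozenset(df["gene_id"])
    positives = frozenset(df["gene_id"][df["label"] == 1])
    rule, methods, excluded, region = "intersection", (), None, None
    if provenance_path is None:
        candidate = Path(str(path) + ".provenance.json")
        provenance_path = candidate if candidate.exists() else None
    if provenance_path is not None:
        doc = json.loads(Path(provenance_path).read_text())
        rule = doc["rule"]
        methods = tuple(doc["method_ids"])
        excluded = doc["excluded_method"]
        if doc.get("region"):
            r = doc["region"]
            upper = float("inf") if r["fc_upper"] == "inf" else r["fc_upper"]
            region = FilterRegion(r["expression_cutoff"], r["fc_lower"], upper)
    return ReferenceStandard(rule=rule, method_ids=methods,
                             excluded_method=excluded, positives=positives,
                             universe=universe, region=region)
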