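"""Layered run configuration: defaults <- YAML file <- CLI flags."""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError
from .filtering import DEFAULT_EXPRESSION_CUTOFFS, DEFAULT_FC_WINDOWS

DEFAULTS: dict = {
    "alpha": 0.05,
    "pseudocount": 0.5,
    "scaling": "total_count",
    "fc_windows": [list(w) for w in DEFAULT_FC_WINDOWS],
    "expression_cutoffs": list(DEFAULT_EXPRESSION_CUTOFFS),
    "target": 0.75,
    "methods": ["pooled_exact", "nb_wald", "rank_sum", "zlogfc"],
    "n_reference_per_condition": 4,
    "n_pairs": 3,
    "rs_rule": "intersection",
    "twcr_dispersion": 0.05,
    "retest_within_window": False,
}


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    """Merge defaults, an optional YAML file, and explicit overrides.

    Precedence is total: an override beats the file beats the default.
    Overrides with value None are ignored (unset CLI flags).
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must be a mapping")
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in DEFAULTS:
            raise ConfigurationError(f"unknown config key {key!r}")
        cfg[key] = value
    return cfg


def parse_windows(raw) -> tuple[tuple[float, float], ...]:
    """Normalise [[1, 1.1], ..., [1.5, "inf"]] into float tuples."""
    out = []
    for lo, hi in raw:
        hi = math.inf if hi in ("inf", "Inf", ".inf") else float(hi)
        out.append((float(lo), hi))
    return tuple(out)


def snapshot(cfg: Mapping, path: str | Path, seed: int | None = None) -> None:
    """Write the frozen config (plus the run's seed) next to an output."""
    doc = {k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
           for k, v in cfg.items()}
    if seed is not None:
        doc["seed"] = seed
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     default=str) + "\n")
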