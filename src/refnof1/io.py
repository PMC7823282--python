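"""On-disk artifacts: count matrices, design tables, DEG tables, reports.

All tabular files are TSV (UTF-8, header row, '.' decimal point); CSV is
accepted behind an explicit ``sep=','``. Gene and sample identifiers are
opaque strings — no symbol mapping is performed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

logger = logging.getLogger(__name__)

#: counts within this distance of an integer are rounded on load (preprocessed
#: public matrices are often stored with float noise); anything further fails.
INTEGER_TOLERANCE = 1e-6


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample raw counts with a two-condition design.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes as rows, samples as columns.
    design
        Mapping sample id -> condition label; exactly two distinct labels.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        counts, design = self.counts, self.design
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = counts.columns[
                [not np.issubdtype(d, np.number) for d in counts.dtypes]
            ]
            raise ValidationError(f"non-numeric counts in samples {list(bad)}")
        if np.any(~np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite count for gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count {values[g, s]} for gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        rounded = np.rint(values)
        off = np.abs(values - rounded)
        if np.any(off > INTEGER_TOLERANCE):
            g, s = np.argwhere(off > INTEGER_TOLERANCE)[0]
            raise ValidationError(
                f"non-integer count {values[g, s]} for gene "
                f"{counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        object.__setattr__(
            self, "counts", pd.DataFrame(rounded.astype(np.int64),
                                         index=counts.index.rename("gene_id"),
                                         columns=counts.columns.rename(None))
        )
        design = pd.Series(design, dtype=object)
        design.index = design.index.astype(str)
        missing = set(map(str, counts.columns)) - set(design.index)
        if missing:
            raise DesignError(f"samples missing from design: {sorted(missing)}")
        extra = set(design.index) - set(map(str, counts.columns))
        if extra:
            raise DesignError(f"design samples not in matrix: {sorted(extra)}")
        levels = sorted(set(design.values))
        if len(levels) != 2:
            raise DesignError(
                f"design must have exactly 2 condition levels, got {levels}"
            )
        object.__setattr__(self, "design", design.loc[counts.columns.astype(str)])

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def condition_labels(self) -> tuple[str, str]:
        """The two condition labels, sorted; the first plays the role of A."""
        a, b = sorted(set(self.design.values))
        return a, b

    def samples_in(self, condition: str) -> list[str]:
        return [s for s, c in self.design.items() if c == condition]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    # -- restriction -------------------------------------------------------

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        keep = [g for g in self.counts.index if g in set(gene_ids)]
        return CountMatrix(self.counts.loc[keep], self.design)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)],
                           self.design.loc[list(sample_ids)])


@dataclass(frozen=True)
class ExternalDEGTable:
    """Per-gene results imported from an external differential-expression tool."""

    method_id: str
    table: pd.DataFrame  # index gene_id; columns log2fc, pvalue, padj


def read_count_matrix(path: str | Path, design_path: str | Path,
                      sep: str = "\t") -> CountMatrix:
    """Load a gene x sample count TSV plus a (sample_id, condition) design TSV.

    The count file's first column must be named ``gene_id``; remaining column
    names are sample ids. Validation failures name the offending gene/sample.
    """
    counts = pd.read_csv(path, sep=sep, dtype={0: str})
    if counts.columns[0] != "gene_id":
        raise ValidationError(
            f"first column of {path} must be 'gene_id', got {counts.columns[0]!r}"
        )
    counts = counts.set_index("gene_id")
    design_df = pd.read_csv(design_path, sep=sep, dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(design_df.columns):
        raise DesignError(
            f"design file must have columns {sorted(required)}, "
            f"got {list(design_df.columns)}"
        )
    design = pd.Series(design_df["condition"].values,
                       index=design_df["sample_id"].values)
    return CountMatrix(counts, design)


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       design_path: str | Path, sep: str = "\t") -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep=sep)
    pd.DataFrame({"sample_id": cm.design.index,
                  "condition": cm.design.values}
                 ).to_csv(design_path, sep=sep, index=False)


def read_deg_table(path: str | Path, method_id: str,
                   sep: str = "\t") -> ExternalDEGTable:
    """Load an external DEG table (gene_id, log2fc, pvalue, padj).

    Rows with a missing p-value or adjusted p-value are dropped with a logged
    count; duplicate gene rows are an error.
    """
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str})
    required = ["gene_id", "log2fc", "pvalue", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"DEG table {path} missing columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate gene rows in {path}: {dup[:10]}")
    n_before = len(df)
    df = df.dropna(subset=["pvalue", "padj"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("read_deg_table(%s): dropped %d rows with missing p-values",
                    method_id, dropped)
    for col in ("pvalue", "padj"):
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            bad = df["gene_id"].to_numpy()[(vals < 0) | (vals > 1)][0]
            raise ValidationError(
                f"{col} outside [0,1] for gene {bad!r} in {path}"
            )
    return ExternalDEGTable(method_id=method_id,
                            table=df.set_index("gene_id")[
                                ["log2fc", "pvalue", "padj"]].astype(float))


def write_deg_table(table: ExternalDEGTable, path: str | Path,
                    sep: str = "\t") -> None:
    table.table.rename_axis("gene_id").to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Evaluation reports


@dataclass(frozen=True)
class PairMetrics:
    """Precision/recall of one hold-out prediction pair against a standard.

    ``precision`` is None when nothing was predicted, ``recall`` is None when
    the standard has no positives (undefined rather than zero).
    """

    pair: tuple[str, str]
    precision: float | None
    recall: float | None
    true_positives: int
    predicted_positives: int
    reference_positives: int
    universe_size: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-pair metrics, their averages, and full provenance for one run."""

    pairs: tuple[PairMetrics, ...]
    average_precision: float | None
    average_recall: float | None
    provenance: Mapping[str, object] = field(default_factory=dict)

    REQUIRED_PROVENANCE = ("rs_rule", "rs_methods", "excluded_method",
                           "prediction_method", "region", "seed")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED_PROVENANCE if k not in self.provenance]
        if missing:
            raise ValidationError(
                f"report provenance missing required keys: {missing}"
            )
        for pm in self.pairs:
            for v in (pm.precision, pm.recall):
                if v is not None and not (0.0 <= v <= 1.0):
                    raise ValidationError(f"metric outside [0,1]: {v}")


def _mean_defined(values: Sequence[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Serialize an evaluation report to a single JSON document (lossless)."""
    doc = {
        "pairs": [dataclasses.asdict(p) | {"pair": list(p.pair)}
                  for p in report.pairs],
        "average_precision": report.average_precision,
        "average_recall": report.average_recall,
        "provenance": dict(report.provenance),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> EvaluationReport:
    doc = json.loads(Path(path).read_text())
    pairs = tuple(
        PairMetrics(
            pair=tuple(p["pair"]),
            precision=p["precision"],
            recall=p["recall"],
            true_positives=p["true_positives"],
            predicted_positives=p["predicted_positives"],
            reference_positives=p["reference_positives"],
            universe_size=p["universe_size"],
        )
        for p in doc["pairs"]
    )
    return EvaluationReport(pairs=pairs,
                            average_precision=doc["average_precision"],
                            average_recall=doc["average_recall"],
                            provenance=doc["provenance"])
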