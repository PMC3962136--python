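"""Reading and writing delimited datasets.

The canonical dialect is TSV with a header row and sample identifiers in the
first column, samples by features; a features-by-samples orientation and CSV
delimiters are accepted and normalized on read.  The outcome comes either
from a named column of the matrix file or from a separate two-column
phenotype file joined on sample ID.  Nominal class labels are coded
0..K-1 in lexicographic label order; ordinal outcomes require an explicit
class order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset

__all__ = ["TableSpec", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class TableSpec:
    """How to interpret a delimited matrix file."""

    path: str
    delimiter: str = "\t"
    orientation: str = "samples-by-features"  # or features-by-samples
    outcome_column: Optional[str] = None  # column of the matrix file
    phenotype_path: Optional[str] = None  # two-column file: sample_id, label
    outcome_kind: str = "nominal"
    class_order: Optional[Sequence] = None  # required iff ordinal

    def __post_init__(self) -> None:
        if self.orientation not in ("samples-by-features", "features-by-samples"):
            raise ValueError("unknown orientation")
        if (self.outcome_column is None) == (self.phenotype_path is None):
            raise ValueError("give exactly one of outcome_column / phenotype_path")
        if self.outcome_kind == "ordinal" and self.class_order is None:
            raise ValueError("ordinal outcomes require an explicit class_order")


def _encode_labels(labels: pd.Series, spec: TableSpec) -> tuple[np.ndarray, list]:
    if spec.class_order is not None:
        order = [str(c) for c in spec.class_order]
    else:
        order = sorted(labels.astype(str).unique())
    code = {lab: i for i, lab in enumerate(order)}
    unknown = set(labels.astype(str)) - set(order)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    return labels.astype(str).map(code).to_numpy(dtype=int), order


def read_dataset(spec: TableSpec) -> LabeledDataset:
    """Load a delimited matrix into a LabeledDataset.

    Rows containing any missing value are dropped with a logged count;
    duplicate sample IDs and non-numeric feature cells raise explicit
    errors naming the offender.
    """
    df = pd.read_csv(spec.path, sep=spec.delimiter, index_col=0)
    if spec.orientation == "features-by-samples":
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID: {dup!r}")

    if spec.outcome_column is not None:
        if spec.outcome_column not in df.columns:
            raise ValueError(f"outcome column {spec.outcome_column!r} not found")
        labels = df[spec.outcome_column]
        feats = df.drop(columns=[spec.outcome_column])
    else:
        pheno = pd.read_csv(
            spec.phenotype_path, sep=spec.delimiter, index_col=0
        ).iloc[:, 0]
        missing = df.index.difference(pheno.index)
        if len(missing):
            raise ValueError(f"no outcome for sample(s): {list(missing[:5])}")
        labels = pheno.loc[df.index]
        feats = df

    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & feats.notna()
    if bad_cells.any().any():
        row = bad_cells.any(axis=1).idxmax()
        col = bad_cells.loc[row].idxmax()
        raise ValueError(f"non-numeric feature cell at sample {row!r}, feature {col!r}")
    complete = ~numeric.isna().any(axis=1) & labels.notna()
    dropped = int((~complete).sum())
    if dropped:
        logger.warning("dropped %d sample(s) with missing values", dropped)
    numeric = numeric.loc[complete]
    labels = labels.loc[complete]

    outcome, order = _encode_labels(labels, spec)
    return LabeledDataset(
        features=numeric.to_numpy(dtype=float),
        outcome=outcome,
        outcome_kind=spec.outcome_kind,
        feature_names=[str(c) for c in numeric.columns],
        class_labels=order,
    )


def write_dataset(
    data: LabeledDataset,
    path: str | Path,
    delimiter: str = "\t",
    outcome_column: str = "outcome",
) -> None:
    """Write a dataset in the canonical samples-by-features dialect; the
    round-trip is lossless to 12 significant digits."""
    df = pd.DataFrame(
        data.features,
        columns=data.feature_names,
        index=[f"s{i}" for i in range(data.n_samples)],
    )
    df.index.name = "sample_id"
    df[outcome_column] = [data.class_labels[c] for c in data.outcome]
    df.to_csv(path, sep=delimiter, float_format="%.12g")
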