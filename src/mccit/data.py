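"""Core data container for continuous-feature / multi-class-outcome studies.

A :class:`LabeledDataset` holds an ``n x p`` matrix of continuous measurements
(e.g. normalized gene-expression values), one integer-coded class label per
sample, and a declaration of whether the outcome is *nominal* (unordered
categories such as cancer subtypes) or *ordinal* (ordered categories such as
tumour stages).  The declaration decides which regression family the
multi-class conditional independence test uses: multinomial logit for nominal
outcomes, ordered logit for ordinal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """Continuous feature matrix plus a multi-class outcome.

    Parameters
    ----------
    features : ndarray, shape (n, p)
        Real-valued measurements, samples by features. No missing values.
    outcome : ndarray, shape (n,)
        Integer class codes in ``{0, ..., K-1}``; every code must occur.
    outcome_kind : {"nominal", "ordinal"}
        Whether class order is meaningful. For ordinal outcomes the codes
        follow the declared order of ``class_labels``.
    feature_names : sequence of str, optional
        One identifier per feature column; defaults to ``f0 .. f{p-1}``.
    class_labels : sequence, optional
        Original labels, one per class code; defaults to ``0 .. K-1``.
    """

    features: np.ndarray
    outcome: np.ndarray
    outcome_kind: str = "nominal"
    feature_names: list[str] = field(default_factory=list)
    class_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D samples x features matrix")
        self.outcome = np.asarray(self.outcome)
        if not np.issubdtype(self.outcome.dtype, np.integer):
            codes = self.outcome.astype(int)
            if not np.array_equal(codes, self.outcome):
                raise ValueError("outcome must contain integer class codes")
            self.outcome = codes
        if self.outcome.ndim != 1 or len(self.outcome) != self.features.shape[0]:
            raise ValueError("outcome length must equal the number of samples")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if self.outcome_kind not in ("nominal", "ordinal"):
            raise ValueError("outcome_kind must be 'nominal' or 'ordinal'")
        k = int(self.outcome.max()) + 1 if len(self.outcome) else 0
        if k < 2:
            raise ValueError("outcome must have at least 2 classes")
        counts = np.bincount(self.outcome, minlength=k)
        if self.outcome.min() < 0 or np.any(counts == 0):
            raise ValueError("class codes must be 0..K-1 with every class present")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must equal the number of features")
        if not self.class_labels:
            self.class_labels = list(range(k))
        if len(self.class_labels) != k:
            raise ValueError("class_labels length must equal the number of classes")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.outcome, minlength=self.n_classes)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "LabeledDataset":
        """Row-subset the dataset (used by cross-validation folds).

        The subset must still contain every class, otherwise the dataset
        invariant fails and a ``ValueError`` propagates.
        """
        rows = np.asarray(rows)
        return LabeledDataset(
            features=self.features[rows],
            outcome=self.outcome[rows],
            outcome_kind=self.outcome_kind,
            feature_names=list(self.feature_names),
            class_labels=list(self.class_labels),
        )
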