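"""Error-matrix accuracy assessment for classified maps.

The error (confusion) matrix cross-tabulates validation samples by their
mapped and reference labels.  Orientation convention, stated explicitly
because the opposite one also circulates in the remote-sensing
literature:

* **rows = mapped class, columns = reference class**;
* user's accuracy is row-wise (of the pixels mapped as class *i*, how
  many really are *i*) and producer's accuracy is column-wise (of the
  reference instances of class *j*, how many were mapped as *j*).

Overall accuracy is the trace fraction, and Cohen's kappa corrects it
for chance agreement: κ = (p_o − p_e)/(1 − p_e) with
p_e = Σ_i (row-sum_i · col-sum_i)/n².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coefficients import ClassLegend, LegendError

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "build_error_matrix",
    "accuracy_report",
]


@dataclass
class ErrorMatrix:
    """Square count matrix: rows = mapped class, columns = reference class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"count matrix shape {self.counts.shape} does not match {n} classes")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("error-matrix entries must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("error-matrix entries must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("error matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="mapped"),
            columns=pd.Index(self.classes, name="reference"),
        )


@dataclass
class AccuracyReport:
    """Overall/user's/producer's accuracy (%) and Cohen's kappa."""

    overall_pct: float
    users_pct: pd.Series  # per mapped class; NaN where the class was never mapped
    producers_pct: pd.Series  # per reference class; NaN where never referenced
    kappa: float  # NaN when chance agreement is 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"users_pct": self.users_pct, "producers_pct": self.producers_pct}
        )
        df.loc["overall"] = [self.overall_pct, self.overall_pct]
        df.loc["kappa"] = [self.kappa, self.kappa]
        return df


def build_error_matrix(
    mapped: Sequence, reference: Sequence, legend: ClassLegend
) -> ErrorMatrix:
    """Tally paired mapped/reference labels into an :class:`ErrorMatrix`.

    Labels may be class names or legend codes; the two lists must be
    non-empty and of equal length.
    """
    mapped = list(mapped)
    reference = list(reference)
    if len(mapped) != len(reference):
        raise ValueError(f"label lists differ in length: {len(mapped)} vs {len(reference)}")
    if not mapped:
        raise ValueError("label lists are empty")

    def normalize(label) -> str:
        if isinstance(label, str):
            if label not in legend.class_names:
                raise LegendError(f"unknown class label: {label!r}")
            return label
        return legend.name_of(int(label))

    names = legend.class_names
    index = {n: i for i, n in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for m, r in zip(mapped, reference):
        counts[index[normalize(m)], index[normalize(r)]] += 1
    return ErrorMatrix(names, counts)


def accuracy_report(em: ErrorMatrix) -> AccuracyReport:
    """Overall, per-class user's/producer's accuracy and Cohen's kappa."""
    counts = em.counts.astype(float)
    n = counts.sum()
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(rows > 0, 100.0 * diag / rows, np.nan)
        producers = np.where(cols > 0, 100.0 * diag / cols, np.nan)

    p_o = diag.sum() / n
    p_e = float(rows @ cols) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else np.nan

    idx = pd.Index(em.classes, name="class")
    return AccuracyReport(
        overall_pct=100.0 * p_o,
        users_pct=pd.Series(users, index=idx, name="users_pct"),
        producers_pct=pd.Series(producers, index=idx, name="producers_pct"),
        kappa=float(kappa),
    )
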