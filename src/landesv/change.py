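"""Between-date land-cover change accounting.

Cross-tabulating two co-registered categorical maps gives the transition
matrix: entry ``[i, j]`` is the area (ha) mapped as class *i* at the first
date and class *j* at the second.  Its diagonal is persistence; for each
class, gain = column sum − diagonal, loss = row sum − diagonal, and
net change = gain − loss.  Period change rates come in two flavours,
both reported: an absolute annual rate (ha · yr⁻¹ = net / years) and a
simple annual percent rate (period percent / years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import LegendError
from .lulc import AreaTable, CategoricalLandscape, GeometryError

__all__ = [
    "TransitionMatrix",
    "ChangeSummary",
    "transition_matrix",
    "gains_losses",
    "change_summary",
]


@dataclass
class TransitionMatrix:
    """From-class × to-class areas (ha) between two dates."""

    classes: tuple[str, ...]
    areas_ha: np.ndarray  # square, [i, j] = area from class i to class j
    date_label_1: str = ""
    date_label_2: str = ""

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.areas_ha = np.asarray(self.areas_ha, dtype=float)
        n = len(self.classes)
        if self.areas_ha.shape != (n, n):
            raise ValueError(f"matrix shape {self.areas_ha.shape} does not match {n} classes")
        if (self.areas_ha < 0).any():
            raise ValueError("transition areas must be non-negative")

    @property
    def row_totals(self) -> AreaTable:
        """Date-1 class areas implied by the matrix."""
        return AreaTable(dict(zip(self.classes, self.areas_ha.sum(axis=1))), self.date_label_1)

    @property
    def col_totals(self) -> AreaTable:
        """Date-2 class areas implied by the matrix."""
        return AreaTable(dict(zip(self.classes, self.areas_ha.sum(axis=0))), self.date_label_2)

    @property
    def persistence(self) -> dict[str, float]:
        return dict(zip(self.classes, np.diag(self.areas_ha)))

    def transpose(self) -> "TransitionMatrix":
        return TransitionMatrix(self.classes, self.areas_ha.T, self.date_label_2, self.date_label_1)

    def row_normalized(self) -> np.ndarray:
        """Row-stochastic transition proportions (rows with area 0 → 0)."""
        rows = self.areas_ha.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(rows > 0, self.areas_ha / rows, 0.0)
        return out

    def to_frame(self, margins: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.areas_ha, index=list(self.classes), columns=list(self.classes))
        if margins:
            diag = np.diag(self.areas_ha)
            df["loss"] = self.areas_ha.sum(axis=1) - diag
            gain = self.areas_ha.sum(axis=0) - diag
            net = gain - df["loss"].to_numpy()[: len(self.classes)]
            df.loc["gain"] = list(gain) + [np.nan]
            df.loc["net"] = list(net) + [np.nan]
        return df


@dataclass
class ChangeSummary:
    """Per-class change accounting over one period.

    ``percent`` is the simple period percent 100·(a₂−a₁)/a₁ (NaN when the
    initial area is 0); ``rate_ha_yr`` = net/years; ``rate_pct_yr`` =
    percent/years.  Gain/loss/persistence are filled only when the summary
    derives from a transition matrix.
    """

    table: pd.DataFrame  # index class; columns see below
    years: float
    date_label_1: str = ""
    date_label_2: str = ""

    COLUMNS = (
        "area_1_ha", "area_2_ha", "gain_ha", "loss_ha", "net_ha",
        "persistence_ha", "percent", "rate_ha_yr", "rate_pct_yr",
    )


def transition_matrix(
    l1: CategoricalLandscape, l2: CategoricalLandscape
) -> TransitionMatrix:
    """Cross-tabulate two co-registered landscapes into area transitions.

    Both landscapes must share grid shape, pixel size and legend.  Pixels
    that are nodata at either date are excluded entirely.
    """
    if l1.shape != l2.shape:
        raise GeometryError(f"grid shapes differ: {l1.shape} vs {l2.shape}")
    if abs(l1.pixel_size_m - l2.pixel_size_m) > 1e-9:
        raise GeometryError("pixel sizes differ")
    if l1.legend.entries != l2.legend.entries:
        raise LegendError("legends differ between the two dates")

    codes = np.asarray(l1.legend.codes)
    valid = l1.valid_mask & l2.valid_mask
    a = l1.grid[valid]
    b = l2.grid[valid]
    # map arbitrary codes onto 0..n-1 legend positions for bincount
    order = np.argsort(codes)
    sorted_codes = codes[order]
    ia = order[np.searchsorted(sorted_codes, a)]
    ib = order[np.searchsorted(sorted_codes, b)]
    n = len(codes)
    counts = np.bincount(ia * n + ib, minlength=n * n).reshape(n, n)
    return TransitionMatrix(
        l1.legend.class_names, counts * l1.pixel_area_ha, l1.date_label, l2.date_label
    )


def gains_losses(tm: TransitionMatrix, years: float | None = None) -> ChangeSummary:
    """Gain/loss/net/persistence per class from a transition matrix.

    gain_j = column sum − diagonal; loss_i = row sum − diagonal;
    net = gain − loss; persistence = diagonal.  Σ gains = Σ losses always
    (both equal the total off-diagonal area).
    """
    diag = np.diag(tm.areas_ha)
    loss = tm.areas_ha.sum(axis=1) - diag
    gain = tm.areas_ha.sum(axis=0) - diag
    a1 = tm.areas_ha.sum(axis=1)
    a2 = tm.areas_ha.sum(axis=0)
    yrs = float(years) if years is not None else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(a1 > 0, 100.0 * (a2 - a1) / a1, np.nan)
    table = pd.DataFrame(
        {
            "area_1_ha": a1,
            "area_2_ha": a2,
            "gain_ha": gain,
            "loss_ha": loss,
            "net_ha": gain - loss,
            "persistence_ha": diag,
            "percent": percent,
            "rate_ha_yr": (gain - loss) / yrs if years else np.nan,
            "rate_pct_yr": percent / yrs if years else np.nan,
        },
        index=pd.Index(tm.classes, name="class"),
    )
    return ChangeSummary(table, yrs, tm.date_label_1, tm.date_label_2)


def change_summary(a1: AreaTable, a2: AreaTable, years: float) -> ChangeSummary:
    """Net change and period rates from two area tables.

    percent = 100·(a₂−a₁)/a₁ (NaN where a₁ = 0); rate_ha_yr = net/years;
    rate_pct_yr = percent/years.
    """
    if years is None or years <= 0:
        raise ValueError("years must be positive")
    if set(a1.class_names) != set(a2.class_names):
        raise ValueError("the two area tables cover different class sets")
    classes = list(a1.class_names)
    v1 = np.array([a1[c] for c in classes])
    v2 = np.array([a2[c] for c in classes])
    net = v2 - v1
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(v1 > 0, 100.0 * net / v1, np.nan)
    table = pd.DataFrame(
        {
            "area_1_ha": v1,
            "area_2_ha": v2,
            "gain_ha": np.nan,
            "loss_ha": np.nan,
            "net_ha": net,
            "persistence_ha": np.nan,
            "percent": percent,
            "rate_ha_yr": net / years,
            "rate_pct_yr": percent / years,
        },
        index=pd.Index(classes, name="class"),
    )
    return ChangeSummary(table, float(years), a1.date_label, a2.date_label)
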