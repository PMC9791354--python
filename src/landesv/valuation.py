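"""Benefit-transfer ecosystem-service valuation.

The total ecosystem service value of a landscape at one date is

    ESV = Σ_k  A_k · VC_k

where ``A_k`` is class *k*'s area (ha) and ``VC_k`` the total coefficient
(USD · ha⁻¹ · yr⁻¹) of its proxy biome.  The decomposition over the 17
individual service functions is

    ESV_f = Σ_k  A_k · VC_fk

and the percent change between two dates is 100 · (ESV_t2 − ESV_t1)/ESV_t1.

All values are computed and stored in USD · yr⁻¹ at full precision;
report helpers print in units of 10⁶ USD rounded to two decimals, and
percent shares are computed on unrounded values before rounding.
Zero-coefficient classes (built-up → urban) participate with value 0
rather than being dropped, so shares and totals stay defined over the
whole landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import ClassLegend, CoefficientTable, LegendError, SERVICE_GROUPS
from .lulc import AreaTable

__all__ = [
    "ESVReport",
    "ESVfReport",
    "ESVChange",
    "UndefinedChangeError",
    "AlignmentError",
    "compute_esv",
    "compute_esvf",
    "esv_percent_change",
    "esv_change_report",
    "MILLION",
]

MILLION = 1e6


class UndefinedChangeError(ValueError):
    """Percent change requested against a zero baseline."""


class AlignmentError(ValueError):
    """Two reports do not cover the same classes/functions."""


@dataclass
class ESVReport:
    """Per-class ecosystem service values for one date.

    ``table`` is indexed by class with columns ``area_ha``,
    ``vc_usd_ha_yr``, ``esv_usd`` and ``share_pct`` (share of the total,
    NaN when the total is 0).
    """

    table: pd.DataFrame
    date_label: str = ""

    @property
    def total(self) -> float:
        """Total ESV in USD · yr⁻¹."""
        return float(self.table["esv_usd"].sum())

    def value(self, class_name: str) -> float:
        return float(self.table.loc[class_name, "esv_usd"])

    def share(self, class_name: str) -> float:
        return float(self.table.loc[class_name, "share_pct"])

    @property
    def entry_names(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def entry_values(self) -> pd.Series:
        return self.table["esv_usd"]

    def in_millions(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["esv_usd"] = (out["esv_usd"] / MILLION).round(decimals)
        out["share_pct"] = out["share_pct"].round(decimals)
        return out


@dataclass
class ESVfReport:
    """Per-function ecosystem service values for one date.

    ``table`` is indexed by function with columns ``group`` and
    ``esvf_usd``; ``group_totals`` sums functions within each of the four
    service groups.
    """

    table: pd.DataFrame
    date_label: str = ""

    @property
    def total(self) -> float:
        return float(self.table["esvf_usd"].sum())

    def value(self, function: str) -> float:
        return float(self.table.loc[function, "esvf_usd"])

    @property
    def group_totals(self) -> pd.Series:
        totals = self.table.groupby("group")["esvf_usd"].sum()
        return totals.reindex([g for g in SERVICE_GROUPS if g in totals.index])

    @property
    def entry_names(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def entry_values(self) -> pd.Series:
        return self.table["esvf_usd"]

    def in_millions(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["esvf_usd"] = (out["esvf_usd"] / MILLION).round(decimals)
        return out


@dataclass
class ESVChange:
    """Absolute and percent ESV change per entry and in total.

    ``table`` is indexed like the input reports with columns ``value_1``,
    ``value_2``, ``change_usd`` and ``percent`` (NaN for zero baselines);
    ``rate_usd_yr`` is the total change divided by the period length.
    """

    table: pd.DataFrame
    years: float
    total_1: float
    total_2: float
    date_label_1: str = ""
    date_label_2: str = ""

    @property
    def total_change(self) -> float:
        return self.total_2 - self.total_1

    @property
    def total_percent(self) -> float:
        return esv_percent_change(self.total_1, self.total_2)

    @property
    def rate_usd_yr(self) -> float:
        return self.total_change / self.years


def _areas_by_biome(areas: AreaTable, legend: ClassLegend) -> tuple[list[str], np.ndarray, list[str]]:
    classes = list(areas.class_names)
    biomes = []
    for c in classes:
        biomes.append(legend.biome_of(c))  # raises LegendError on unmapped class
    return classes, np.array([areas[c] for c in classes], dtype=float), biomes


def compute_esv(
    areas: AreaTable, coeffs: CoefficientTable, legend: ClassLegend
) -> ESVReport:
    """Total and per-class ESV = A_k · VC_k of each class's proxy biome."""
    classes, a, biomes = _areas_by_biome(areas, legend)
    missing = sorted(set(biomes) - set(coeffs.totals.index))
    if missing:
        raise LegendError(f"biomes absent from coefficient table: {missing}")
    vc = np.array([coeffs.vc(b) for b in biomes])
    esv = a * vc
    total = esv.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        share = 100.0 * esv / total if total > 0 else np.full_like(esv, np.nan)
    table = pd.DataFrame(
        {"area_ha": a, "vc_usd_ha_yr": vc, "esv_usd": esv, "share_pct": share},
        index=pd.Index(classes, name="class"),
    )
    return ESVReport(table, areas.date_label)


def compute_esvf(
    areas: AreaTable, coeffs: CoefficientTable, legend: ClassLegend
) -> ESVfReport:
    """Per-function ESV_f = Σ_k A_k · VC_fk, with group subtotals."""
    classes, a, biomes = _areas_by_biome(areas, legend)
    missing = sorted(set(biomes) - set(coeffs.per_function.columns))
    if missing:
        raise LegendError(f"biomes absent from coefficient table: {missing}")
    # per-function value: matrix (functions × biomes) times biome area vector
    biome_area = pd.Series(0.0, index=coeffs.per_function.columns)
    for b, area in zip(biomes, a):
        biome_area[b] += area
    esvf = coeffs.per_function.to_numpy() @ biome_area.to_numpy()
    table = pd.DataFrame(
        {"group": coeffs.groups.to_numpy(), "esvf_usd": esvf},
        index=coeffs.per_function.index.copy(),
    )
    return ESVfReport(table, areas.date_label)


def esv_percent_change(v1: float, v2: float) -> float:
    """100 · (v2 − v1)/v1; positive means the service value increased."""
    if v1 == 0:
        raise UndefinedChangeError("percent change undefined for zero baseline value")
    return 100.0 * (v2 - v1) / v1


def esv_change_report(
    r1: ESVReport | ESVfReport, r2: ESVReport | ESVfReport, years: float
) -> ESVChange:
    """Entry-wise and total ESV change between two same-kind reports."""
    if years is None or years <= 0:
        raise ValueError("years must be positive")
    if type(r1) is not type(r2):
        raise AlignmentError("reports are of different kinds")
    if set(r1.entry_names) != set(r2.entry_names):
        raise AlignmentError("reports cover different classes/functions")
    names = list(r1.entry_names)
    v1 = r1.entry_values().reindex(names).to_numpy(dtype=float)
    v2 = r2.entry_values().reindex(names).to_numpy(dtype=float)
    change = v2 - v1
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(v1 != 0, 100.0 * change / v1, np.nan)
    table = pd.DataFrame(
        {
            "value_1": v1,
            "value_2": v2,
            "change_usd": change,
            "percent": percent,
            "rate_usd_yr": change / years,
        },
        index=pd.Index(names, name=r1.table.index.name or "entry"),
    )
    return ESVChange(
        table, float(years), float(v1.sum()), float(v2.sum()), r1.date_label, r2.date_label
    )
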