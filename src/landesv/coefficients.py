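"""Benefit-transfer value-coefficient tables and the class→biome legend.

Benefit transfer values a landscape by multiplying each land-cover class's
area by a per-hectare coefficient estimated for an equivalent biome
(USD · ha⁻¹ · yr⁻¹).  Two tables are involved:

* a per-biome **total** coefficient ``VC_k`` — the full annual value of one
  hectare of that biome's ecosystem services; and
* a per-function matrix ``VC_fk`` decomposing that total over 17 individual
  service functions, each belonging to one of four groups: provisioning
  (PES), regulating (RES), supporting (SES) and cultural (CES).

A :class:`ClassLegend` maps mapped land-cover classes onto the biome whose
coefficients stand proxy for them (e.g. both forest and shrubland use the
tropical-forest coefficients; built-up uses the urban biome, valued 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SERVICE_GROUPS",
    "GROUP_CODES",
    "ClassLegend",
    "CoefficientTable",
    "LegendError",
    "CoefficientFormatError",
    "load_legend",
    "load_coefficient_table",
    "write_coefficient_table",
    "validate_column_sums",
]

#: Canonical service-group names, in reporting order.
SERVICE_GROUPS = ("provisioning", "regulating", "supporting", "cultural")

#: Conventional short codes for the four groups.
GROUP_CODES = {
    "provisioning": "PES",
    "regulating": "RES",
    "supporting": "SES",
    "cultural": "CES",
}

#: Name of the totals row in a coefficient CSV.
TOTAL_ROW = "TOTAL"


class LegendError(ValueError):
    """A class/biome name is absent from, or inconsistent with, the legend."""


class CoefficientFormatError(ValueError):
    """A coefficient or legend file violates the documented CSV format."""


@dataclass(frozen=True)
class ClassLegend:
    """Ordered mapping of integer class codes to class and biome names.

    Parameters
    ----------
    entries
        Sequence of ``(code, class_name, biome_name)`` triples.  Codes and
        class names must be unique; every class maps to exactly one biome
        (several classes may share a biome).
    """

    entries: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((int(c), str(n), str(b)) for c, n, b in self.entries))
        codes = [c for c, _, _ in self.entries]
        names = [n for _, n, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise LegendError("class codes must be unique")
        if len(set(names)) != len(names):
            raise LegendError("class names must be unique")
        if not self.entries:
            raise LegendError("legend is empty")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _, _ in self.entries)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(n for _, n, _ in self.entries)

    @property
    def biomes(self) -> tuple[str, ...]:
        """Biome names in first-appearance order, deduplicated."""
        seen: dict[str, None] = {}
        for _, _, b in self.entries:
            seen.setdefault(b)
        return tuple(seen)

    def code_of(self, class_name: str) -> int:
        for c, n, _ in self.entries:
            if n == class_name:
                return c
        raise LegendError(f"unknown class name: {class_name!r}")

    def name_of(self, code: int) -> str:
        for c, n, _ in self.entries:
            if c == code:
                return n
        raise LegendError(f"unknown class code: {code}")

    def biome_of(self, class_name: str) -> str:
        for _, n, b in self.entries:
            if n == class_name:
                return b
        raise LegendError(f"unknown class name: {class_name!r}")

    def classes_of_biome(self, biome: str) -> tuple[str, ...]:
        return tuple(n for _, n, b in self.entries if b == biome)


@dataclass
class CoefficientTable:
    """Per-biome total (``VC_k``) and per-function (``VC_fk``) coefficients.

    Attributes
    ----------
    per_function
        DataFrame indexed by function name, one column per biome, values in
        USD · ha⁻¹ · yr⁻¹.  Missing cells are stored as 0.
    groups
        Series mapping each function name to its service group (one of
        :data:`SERVICE_GROUPS`).
    totals
        Series of ``VC_k`` per biome (USD · ha⁻¹ · yr⁻¹).
    currency, unit
        Metadata strings carried through to reports.
    """

    per_function: pd.DataFrame
    groups: pd.Series
    totals: pd.Series
    currency: str = "USD"
    unit: str = "USD ha-1 yr-1"

    def __post_init__(self) -> None:
        self.per_function = self.per_function.astype(float)
        self.totals = self.totals.astype(float)
        if (self.per_function.to_numpy() < 0).any() or (self.totals.to_numpy() < 0).any():
            raise CoefficientFormatError("coefficients must be non-negative")
        if self.per_function.index.duplicated().any():
            raise CoefficientFormatError("function names must be unique")
        bad = set(self.groups) - set(SERVICE_GROUPS)
        if bad:
            raise CoefficientFormatError(f"unknown service groups: {sorted(bad)}")
        if list(self.groups.index) != list(self.per_function.index):
            raise CoefficientFormatError("groups index must match per_function index")

    @property
    def biomes(self) -> tuple[str, ...]:
        return tuple(self.per_function.columns)

    @property
    def functions(self) -> tuple[str, ...]:
        return tuple(self.per_function.index)

    def vc(self, biome: str) -> float:
        """Total coefficient VC_k for one biome."""
        if biome not in self.totals.index:
            raise LegendError(f"biome not in table: {biome!r}")
        return float(self.totals[biome])

    def scaled(self, biome: str, factor: float) -> "CoefficientTable":
        """Return a copy with one biome's total and per-function cells scaled.

        Scaling the whole column by the same factor keeps the total-based
        and function-based valuations mutually consistent.
        """
        pf = self.per_function.copy()
        tot = self.totals.copy()
        pf[biome] = pf[biome] * factor
        tot[biome] = tot[biome] * factor
        return CoefficientTable(pf, self.groups.copy(), tot, self.currency, self.unit)


def load_legend(path: str | Path) -> ClassLegend:
    """Read a legend CSV with columns ``code,class_name,biome_name``."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    required = {"code", "class_name", "biome_name"}
    if not required.issubset(df.columns):
        raise CoefficientFormatError(f"legend CSV needs columns {sorted(required)}")
    return ClassLegend(tuple(zip(df["code"].astype(int), df["class_name"], df["biome_name"])))


def _parse_cell(raw, row: str, col: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return 0.0  # missing cells read as 0
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise CoefficientFormatError(f"unparseable cell at function {row!r}, biome {col!r}: {raw!r}")
    if value < 0:
        raise CoefficientFormatError(f"negative coefficient at function {row!r}, biome {col!r}: {value}")
    return value


def load_coefficient_table(path: str | Path | io.IOBase, legend: ClassLegend) -> CoefficientTable:
    """Read a coefficient CSV (``function,group,<biome>,...`` + TOTAL row).

    The final row, named ``TOTAL``, holds the per-biome totals ``VC_k``.
    Missing numeric cells are read as 0.  Every biome the legend maps to
    must be present as a column.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True, dtype=str)
    if "function" not in df.columns or "group" not in df.columns:
        raise CoefficientFormatError("coefficient CSV needs 'function' and 'group' columns")
    biome_cols = [c for c in df.columns if c not in ("function", "group")]
    missing = set(legend.biomes) - set(biome_cols)
    if missing:
        raise LegendError(f"biome columns absent from coefficient CSV: {sorted(missing)}")

    body = df[df["function"] != TOTAL_ROW]
    total_rows = df[df["function"] == TOTAL_ROW]
    if len(total_rows) != 1:
        raise CoefficientFormatError("coefficient CSV must contain exactly one TOTAL row")

    per_function = pd.DataFrame(
        {b: [_parse_cell(v, f, b) for f, v in zip(body["function"], body[b])] for b in biome_cols},
        index=pd.Index(body["function"], name="function"),
    )
    totals = pd.Series(
        {b: _parse_cell(total_rows.iloc[0][b], TOTAL_ROW, b) for b in biome_cols}, name="VC_k"
    )
    groups = pd.Series(list(body["group"]), index=per_function.index, name="group")
    return CoefficientTable(per_function, groups, totals)


def write_coefficient_table(table: CoefficientTable, path: str | Path) -> None:
    """Write a coefficient table back to the documented CSV layout."""
    out = table.per_function.copy()
    out.insert(0, "group", table.groups)
    total = {b: table.totals[b] for b in table.biomes}
    total["group"] = ""
    out = pd.concat([out, pd.DataFrame(total, index=pd.Index([TOTAL_ROW], name="function"))])
    out.to_csv(path)


def validate_column_sums(
    table: CoefficientTable, tolerance: float = 0.01
) -> list[tuple[str, float]]:
    """Report biomes whose per-function column sum deviates from VC_k.

    Returns ``(biome, |Σ_f VC_fk − VC_k|)`` for every biome deviating by
    more than ``tolerance``; an empty list means the table is internally
    consistent.  Consistency is reported, never enforced: published tables
    are not always exactly recomputable, and valuation stays well-defined
    either way.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    deviations = (table.per_function.sum(axis=0) - table.totals).abs()
    return [(b, float(d)) for b, d in deviations.items() if d > tolerance]
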