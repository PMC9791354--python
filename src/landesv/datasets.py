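"""Built-in reference tables for the Guna Mountain study system.

These small CSVs ship with the package so the whole pipeline can be run
desk-side, with no raster inputs: the class legend with its biome
proxies, the benefit-transfer coefficient tables, the published class
areas for 1995/2008/2020, and the 1995→2020 transition matrix.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .change import TransitionMatrix
from .coefficients import ClassLegend, CoefficientTable, load_coefficient_table, load_legend
from .lulc import AreaTable, read_area_table

__all__ = [
    "GUNA_YEARS",
    "data_path",
    "guna_legend",
    "guna_coefficients",
    "guna_areas",
    "guna_area_tables",
    "guna_transition_1995_2020",
]

#: Mapping dates of the built-in Guna area tables.
GUNA_YEARS = ("1995", "2008", "2020")


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(importlib.resources.files("landesv").joinpath("data").joinpath(name)))


def guna_legend() -> ClassLegend:
    """Five-class legend with biome proxies (shrubland+forest → tropical forest)."""
    return load_legend(data_path("guna_legend.csv"))


def guna_coefficients(legend: ClassLegend | None = None) -> CoefficientTable:
    """The built-in coefficient table (totals VC_k and per-function VC_fk)."""
    return load_coefficient_table(data_path("guna_coefficients.csv"), legend or guna_legend())


def guna_areas(year: str | int, legend: ClassLegend | None = None) -> AreaTable:
    """Published class areas (ha) for one mapping year (1995, 2008 or 2020)."""
    year = str(year)
    if year not in GUNA_YEARS:
        raise ValueError(f"no built-in area table for {year!r}; have {GUNA_YEARS}")
    return read_area_table(data_path(f"guna_areas_{year}.csv"), legend or guna_legend(), year)


def guna_area_tables(legend: ClassLegend | None = None) -> dict[str, AreaTable]:
    legend = legend or guna_legend()
    return {y: guna_areas(y, legend) for y in GUNA_YEARS}


def guna_transition_1995_2020(legend: ClassLegend | None = None) -> TransitionMatrix:
    """Published 1995→2020 transition areas (ha), 10-ha cell granularity."""
    legend = legend or guna_legend()
    df = pd.read_csv(data_path("guna_transition_1995_2020.csv"), comment="#", index_col=0)
    classes = list(legend.class_names)
    mat = df.loc[classes, classes].to_numpy(dtype=float)
    return TransitionMatrix(tuple(classes), np.asarray(mat), "1995", "2020")
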