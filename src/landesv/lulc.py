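"""Categorical landscapes, raster/tabular I/O and class-area accounting.

A :class:`CategoricalLandscape` is a rectangular, north-up, row-major grid
of small integer class codes with a square pixel size in metres.  All the
downstream statistics in this package (areas, transitions, valuation) are
functions of pixel counts only, so geo-registration beyond the pixel size
is carried as opaque metadata and never interpreted.

Supported raster formats are single-band integer TIFF (pixel size read
from the GeoTIFF ModelPixelScale tag when present, nodata from the
GDAL_NODATA tag) and ESRI ASCII grid (.asc / .agr), whose plain-text
header carries ``cellsize`` and ``NODATA_value`` natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coefficients import ClassLegend, LegendError

__all__ = [
    "CategoricalLandscape",
    "AreaTable",
    "GeometryError",
    "UnsupportedInputError",
    "AreaFormatError",
    "read_landscape",
    "write_landscape",
    "areas_from_landscape",
    "read_area_table",
    "write_area_table",
]

M2_PER_HA = 10_000.0

# GeoTIFF / GDAL private tags used to round-trip pixel size and nodata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_GDAL_NODATA = 42113


class GeometryError(ValueError):
    """Grid shapes or pixel geometries are unusable or mismatched."""


class UnsupportedInputError(ValueError):
    """The raster is not a single-band square-pixel integer grid."""


class AreaFormatError(ValueError):
    """An area CSV violates the documented format."""


@dataclass
class CategoricalLandscape:
    """Integer-coded class grid with pixel size, nodata code and legend."""

    grid: np.ndarray
    pixel_size_m: float
    legend: ClassLegend
    date_label: str = ""
    nodata_code: int = -1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise GeometryError("grid must be a non-empty 2-D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise UnsupportedInputError(f"grid dtype must be integer, got {self.grid.dtype}")
        if self.pixel_size_m <= 0:
            raise GeometryError("pixel_size_m must be positive")
        if self.nodata_code in self.legend.codes:
            raise LegendError("nodata code collides with a legend class code")
        present = np.unique(self.grid)
        unknown = sorted(set(present.tolist()) - set(self.legend.codes) - {self.nodata_code})
        if unknown:
            raise LegendError(f"grid contains codes absent from legend: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size_m**2 / M2_PER_HA

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata_code

    def class_counts(self) -> dict[str, int]:
        """Pixel count per legend class (nodata excluded; absent classes 0)."""
        valid = self.grid[self.valid_mask]
        return {
            name: int(np.count_nonzero(valid == code))
            for code, name in zip(self.legend.codes, self.legend.class_names)
        }


@dataclass
class AreaTable:
    """Per-class area in hectares for one date (the A_k of the valuation)."""

    areas: dict[str, float]
    date_label: str = ""

    def __post_init__(self) -> None:
        self.areas = {str(k): float(v) for k, v in self.areas.items()}
        for name, a in self.areas.items():
            if a < 0:
                raise AreaFormatError(f"negative area for class {name!r}: {a}")

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.areas)

    def __getitem__(self, class_name: str) -> float:
        return self.areas[class_name]

    def rounded(self, nearest_ha: float = 10.0) -> "AreaTable":
        """Areas rounded to the nearest ``nearest_ha`` for reporting.

        Internally everything is kept at full precision; reports round to
        10 ha by default, which is the granularity published regional
        land-cover tables commonly use.
        """
        return AreaTable(
            {k: round(v / nearest_ha) * nearest_ha for k, v in self.areas.items()},
            self.date_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class_name": list(self.areas), "area_ha": list(self.areas.values())}
        )


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, int | None]:
    """Parse an ESRI ASCII grid; returns (grid, cellsize, nodata)."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise UnsupportedInputError(f"ASCII grid missing {req!r} header")
    grid = np.loadtxt(data_lines, dtype=np.int64, ndmin=2)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GeometryError(
            f"ASCII grid body {grid.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = int(header["nodata_value"]) if "nodata_value" in header else None
    return grid, float(header["cellsize"]), nodata


def _write_ascii_grid(landscape: CategoricalLandscape, path: Path) -> None:
    r, c = landscape.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {c}\nnrows {r}\nxllcorner 0.0\nyllcorner 0.0\n")
        fh.write(f"cellsize {landscape.pixel_size_m}\nNODATA_value {landscape.nodata_code}\n")
        np.savetxt(fh, landscape.grid, fmt="%d")


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None, int | None]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1 or len(tif.pages) > 1:
            raise UnsupportedInputError("multi-band raster; expected a single-band class grid")
        grid = page.asarray()
        pixel = nodata = None
        if _TAG_MODEL_PIXEL_SCALE in page.tags:
            sx, sy = page.tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            if abs(sx - sy) > 1e-9 * max(abs(sx), abs(sy)):
                raise GeometryError(f"non-square pixels: {sx} x {sy} m")
            pixel = float(sx)
        if _TAG_GDAL_NODATA in page.tags:
            nodata = int(float(page.tags[_TAG_GDAL_NODATA].value))
    if not np.issubdtype(grid.dtype, np.integer):
        raise UnsupportedInputError(f"raster dtype {grid.dtype} is not integer")
    return grid.astype(np.int64), pixel, nodata


def read_landscape(
    path: str | Path,
    legend: ClassLegend,
    date_label: str = "",
    *,
    pixel_size_m: float | None = None,
    nodata_code: int | None = None,
) -> CategoricalLandscape:
    """Read a single-band integer raster (TIFF or ESRI ASCII grid).

    Pixel size and nodata come from raster metadata where available; the
    keyword arguments override (and are required for bare TIFFs written
    without geographic tags).
    """
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd", ".txt"):
        grid, meta_pixel, meta_nodata = _read_ascii_grid(path)
    else:
        grid, meta_pixel, meta_nodata = _read_tiff(path)
    pixel = pixel_size_m if pixel_size_m is not None else meta_pixel
    if pixel is None:
        raise GeometryError("pixel size not present in raster metadata; pass pixel_size_m")
    nodata = nodata_code if nodata_code is not None else meta_nodata
    if nodata is None:
        nodata = -1
    return CategoricalLandscape(grid, pixel, legend, date_label, nodata)


def write_landscape(landscape: CategoricalLandscape, path: str | Path) -> None:
    """Write a landscape as TIFF (.tif) or ESRI ASCII grid (.asc).

    TIFF output embeds the pixel size (ModelPixelScale) and nodata
    (GDAL_NODATA) tags so :func:`read_landscape` round-trips losslessly.
    """
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd", ".txt"):
        _write_ascii_grid(landscape, path)
        return
    px = float(landscape.pixel_size_m)
    nodata_ascii = (str(landscape.nodata_code) + "\x00").encode()
    tifffile.imwrite(
        path,
        landscape.grid.astype(np.int32),
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
            (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii),
        ],
    )


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def areas_from_landscape(landscape: CategoricalLandscape) -> AreaTable:
    """Class areas in hectares: pixel count × pixel_size² / 10⁴.

    Nodata pixels are excluded from every class and from the total;
    legend classes absent from the grid get area 0.
    """
    pa = landscape.pixel_area_ha
    counts = landscape.class_counts()
    return AreaTable({name: n * pa for name, n in counts.items()}, landscape.date_label)


def read_area_table(path: str | Path, legend: ClassLegend, date_label: str = "") -> AreaTable:
    """Read a ``class_name,area_ha`` CSV into an :class:`AreaTable`."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    if not {"class_name", "area_ha"}.issubset(df.columns):
        raise AreaFormatError("area CSV needs columns class_name,area_ha")
    if len(df) == 0:
        raise AreaFormatError("area CSV has no class rows")
    if df["class_name"].duplicated().any():
        dups = sorted(df.loc[df["class_name"].duplicated(), "class_name"])
        raise AreaFormatError(f"duplicate class rows: {dups}")
    unknown = sorted(set(df["class_name"]) - set(legend.class_names))
    if unknown:
        raise LegendError(f"unknown class names in area CSV: {unknown}")
    try:
        values = df["area_ha"].astype(float)
    except ValueError as exc:
        raise AreaFormatError(f"unparseable area cell: {exc}") from exc
    return AreaTable(dict(zip(df["class_name"], values)), date_label)


def write_area_table(table: AreaTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)
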