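"""Synthetic landscapes, reference samples and spectral bands.

Every input the pipeline consumes can be generated here, so the whole
chain is testable without any satellite download: two-date categorical
landscapes with controlled composition and per-pixel Markov transition
structure, confusion-corrupted validation samples, and per-class
Gaussian reflectance bands.

Pixels are drawn independently (optionally smoothed by a few passes of
3×3 majority filtering for visual coherence).  That is deliberately
simpler than real landscape pattern: every downstream statistic in this
package — areas, transition tallies, valuation, accuracy — depends only
on pixel counts, not on spatial arrangement.

The shipped default configuration (``data/guna_generator.yaml``)
emulates the Guna Mountain study system: the 1995 class composition
(cropland 0.457, shrubland 0.300, grassland 0.195, forest 0.042,
built-up 0.006), the observed 1995→2020 transition structure
row-normalized into a Markov matrix, a confusion matrix with 0.87
diagonal (the magnitude reported for such maps), and band means that
order NDVI as forest > grassland > built-up.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .coefficients import ClassLegend
from .indices import BandGrid, STANDARD_BANDS
from .lulc import CategoricalLandscape

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "SamplingError",
    "default_config",
    "generate_landscape",
    "apply_markov_change",
    "generate_reference_sample",
    "generate_bands",
]

_ROW_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """The generator configuration violates its invariants."""


class SamplingError(ValueError):
    """A sample request cannot be satisfied (e.g. n exceeds pixel count)."""


@dataclass
class GeneratorConfig:
    """Everything needed to synthesise a multi-date study system.

    Attributes
    ----------
    legend
        Class codes/names/biomes of the synthetic landscape.
    shape
        Grid (rows, cols).
    pixel_size_m
        Square pixel side in metres (default 30, the Landsat class size).
    proportions
        Initial-date class fractions (class name → fraction, summing to 1).
    transition
        Row-stochastic per-pixel transition probabilities, class → class.
    confusion
        Row-stochastic reference-label confusion probabilities,
        mapped class → reference class.
    band_params
        Per class, per band name: ``(mean, spread)`` of the reflectance
        distribution (normal, truncated at 0).
    smoothing_passes
        Number of 3×3 majority-filter passes applied after the i.i.d.
        draw (0 = none).
    seed
        Default random seed; every operation also accepts an override.
    """

    legend: ClassLegend
    shape: tuple[int, int] = (200, 200)
    pixel_size_m: float = 30.0
    proportions: dict[str, float] = field(default_factory=dict)
    transition: dict[str, dict[str, float]] = field(default_factory=dict)
    confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    band_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    smoothing_passes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        names = self.legend.class_names
        if self.proportions:
            unknown = set(self.proportions) - set(names)
            if unknown:
                raise ConfigError(f"proportions name unknown classes: {sorted(unknown)}")
            total = sum(self.proportions.values())
            if abs(total - 1.0) > _ROW_SUM_TOL:
                raise ConfigError(f"class proportions sum to {total!r}, not 1")
            if any(p < 0 for p in self.proportions.values()):
                raise ConfigError("proportions must be non-negative")
        for label, rows in (("transition", self.transition), ("confusion", self.confusion)):
            for cls, row in rows.items():
                if cls not in names:
                    raise ConfigError(f"{label} row for unknown class {cls!r}")
                s = sum(row.values())
                if abs(s - 1.0) > _ROW_SUM_TOL:
                    raise ConfigError(f"{label} row for {cls!r} sums to {s!r}, not 1")
                if any(p < 0 for p in row.values()):
                    raise ConfigError(f"{label} row for {cls!r} has negative entries")

    # -- matrix views aligned to legend order --------------------------------
    def proportion_vector(self) -> np.ndarray:
        return np.array([self.proportions.get(n, 0.0) for n in self.legend.class_names])

    def _row_matrix(self, rows: dict[str, dict[str, float]]) -> np.ndarray:
        names = self.legend.class_names
        mat = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            row = rows.get(a)
            if row is None:  # absent row = identity (class never changes)
                mat[i, i] = 1.0
                continue
            for j, b in enumerate(names):
                mat[i, j] = row.get(b, 0.0)
        return mat

    def transition_matrix(self) -> np.ndarray:
        return self._row_matrix(self.transition)

    def confusion_matrix(self) -> np.ndarray:
        return self._row_matrix(self.confusion)

    # -- YAML round-trip ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from the documented YAML schema.

        Schema (all keys optional except ``classes``)::

            classes: [{code: 1, name: forest, biome: tropical forest}, ...]
            shape: [rows, cols]
            pixel_size_m: 30
            proportions: {forest: 0.042, ...}           # sum to 1
            transition_weights: {forest: {forest: 2090, ...}, ...}
            confusion: {forest: {forest: 0.87, ...}, ...}
            bands: {forest: {green: [0.05, 0.01], ...}, ...}
            smoothing_passes: 0
            seed: 0

        ``transition_weights`` rows are relative weights (e.g. observed
        transition areas) normalized to probabilities at load time;
        a ``transition`` key may instead give probabilities directly.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        legend = ClassLegend(
            tuple((c["code"], c["name"], c["biome"]) for c in raw["classes"])
        )
        transition = raw.get("transition", {})
        for name, row in raw.get("transition_weights", {}).items():
            total = float(sum(row.values()))
            if total <= 0:
                raise ConfigError(f"transition_weights row for {name!r} sums to {total}")
            transition[name] = {k: v / total for k, v in row.items()}
        bands = {
            name: {band: tuple(map(float, ms)) for band, ms in per.items()}
            for name, per in raw.get("bands", {}).items()
        }
        return cls(
            legend=legend,
            shape=tuple(raw.get("shape", (200, 200))),
            pixel_size_m=float(raw.get("pixel_size_m", 30.0)),
            proportions={k: float(v) for k, v in raw.get("proportions", {}).items()},
            transition=transition,
            confusion=raw.get("confusion", {}),
            band_params=bands,
            smoothing_passes=int(raw.get("smoothing_passes", 0)),
            seed=int(raw.get("seed", 0)),
        )


def default_config() -> GeneratorConfig:
    """The shipped Guna-like configuration (see module docstring)."""
    path = importlib.resources.files("landesv").joinpath("data/guna_generator.yaml")
    return GeneratorConfig.from_yaml(str(path))


def _majority_filter(grid: np.ndarray, codes: np.ndarray, passes: int) -> np.ndarray:
    """k passes of 3×3 majority voting; ties keep the centre pixel's class."""
    for _ in range(passes):
        votes = np.zeros((len(codes),) + grid.shape, dtype=np.int16)
        padded = np.pad(grid, 1, mode="edge")
        for di in (0, 1, 2):
            for dj in (0, 1, 2):
                window = padded[di : di + grid.shape[0], dj : dj + grid.shape[1]]
                for k, code in enumerate(codes):
                    votes[k] += window == code
        pos = np.zeros(grid.shape, dtype=np.int64)
        for k, code in enumerate(codes):
            pos[grid == code] = k
        centre_votes = np.take_along_axis(votes, pos[None], axis=0)[0]
        winner = codes[np.argmax(votes, axis=0)]
        grid = np.where(centre_votes == votes.max(axis=0), grid, winner)
    return grid


def generate_landscape(
    cfg: GeneratorConfig, date_label: str = "", seed: int | None = None
) -> CategoricalLandscape:
    """Draw each pixel's class i.i.d. from the configured proportions."""
    if not cfg.proportions:
        raise ConfigError("config has no class proportions")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    codes = np.asarray(cfg.legend.codes)
    p = cfg.proportion_vector()
    grid = rng.choice(codes, size=cfg.shape, p=p)
    if cfg.smoothing_passes:
        grid = _majority_filter(grid, codes, cfg.smoothing_passes)
    return CategoricalLandscape(grid.astype(np.int64), cfg.pixel_size_m, cfg.legend, date_label)


def apply_markov_change(
    landscape: CategoricalLandscape,
    P: np.ndarray | dict[str, dict[str, float]],
    seed: int = 0,
    date_label: str = "",
) -> CategoricalLandscape:
    """Transition every pixel independently per its class's row of ``P``.

    ``P`` is row-stochastic over the legend's classes (legend order when
    given as an array).  Nodata pixels are left untouched.
    """
    legend = landscape.legend
    names = legend.class_names
    if isinstance(P, dict):
        mat = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                mat[i, j] = P.get(a, {}).get(b, 1.0 if i == j else 0.0)
    else:
        mat = np.asarray(P, dtype=float)
    if mat.shape != (len(names), len(names)):
        raise ConfigError(f"transition matrix shape {mat.shape} does not match legend")
    if (mat < 0).any() or np.abs(mat.sum(axis=1) - 1.0).max() > _ROW_SUM_TOL:
        raise ConfigError("transition matrix rows must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    codes = np.asarray(legend.codes)
    order = np.argsort(codes)
    grid = landscape.grid
    valid = landscape.valid_mask
    idx = order[np.searchsorted(codes[order], grid[valid])]
    cum = np.cumsum(mat, axis=1)
    cum[:, -1] = 1.0  # guard against floating-point shortfall
    u = rng.random(idx.shape)
    new_idx = (u[:, None] >= cum[idx]).sum(axis=1)
    out = grid.copy()
    out[valid] = codes[new_idx]
    return CategoricalLandscape(
        out, landscape.pixel_size_m, legend, date_label or landscape.date_label,
        landscape.nodata_code,
    )


def _proportional_allocation(counts: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` samples over class counts."""
    total = counts.sum()
    quota = n * counts / total
    alloc = np.floor(quota).astype(np.int64)
    remainder = n - alloc.sum()
    if remainder > 0:
        frac_order = np.argsort(-(quota - alloc), kind="stable")
        alloc[frac_order[:remainder]] += 1
    # never allocate more samples to a class than it has pixels
    overflow = np.maximum(alloc - counts, 0)
    while overflow.sum() > 0:
        alloc -= overflow
        spare = counts - alloc
        give_order = np.argsort(-spare, kind="stable")
        for k in give_order:
            take = min(int(overflow.sum()), int(spare[k]))
            alloc[k] += take
            overflow = np.zeros_like(overflow)
            if alloc.sum() == n:
                break
        overflow = np.maximum(alloc - counts, 0)
    return alloc


def generate_reference_sample(
    landscape: CategoricalLandscape,
    confusion: np.ndarray | dict[str, dict[str, float]],
    n: int,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Draw paired mapped/reference labels for accuracy assessment.

    ``n`` pixel positions are allocated to classes proportionally to
    their pixel counts (largest-remainder rule, so class counts match
    proportions to within one sample) and sampled without replacement.
    Each sample's mapped label is its pixel's class; its reference label
    is drawn from the confusion row of that class — emulating an
    independent validation campaign with known per-class reliability.
    """
    if n < 1:
        raise SamplingError("sample size must be at least 1")
    legend = landscape.legend
    names = legend.class_names
    if isinstance(confusion, dict):
        mat = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                mat[i, j] = confusion.get(a, {}).get(b, 1.0 if i == j else 0.0)
    else:
        mat = np.asarray(confusion, dtype=float)
    if (mat < 0).any() or np.abs(mat.sum(axis=1) - 1.0).max() > _ROW_SUM_TOL:
        raise ConfigError("confusion matrix rows must be non-negative and sum to 1")

    counts = np.array([landscape.class_counts()[nm] for nm in names])
    if n > counts.sum():
        raise SamplingError(f"requested {n} samples but only {counts.sum()} valid pixels")
    alloc = _proportional_allocation(counts, n)

    rng = np.random.default_rng(seed)
    mapped: list[str] = []
    reference: list[str] = []
    flat = landscape.grid.ravel()
    for i, nm in enumerate(names):
        if alloc[i] == 0:
            continue
        positions = np.flatnonzero(flat == legend.codes[i])
        chosen = rng.choice(positions, size=alloc[i], replace=False)
        ref_idx = rng.choice(len(names), size=alloc[i], p=mat[i])
        mapped.extend(nm for _ in chosen)  # every chosen pixel carries class nm
        reference.extend(names[j] for j in ref_idx)
    return mapped, reference


def generate_bands(
    landscape: CategoricalLandscape, cfg: GeneratorConfig, seed: int | None = None
) -> BandGrid:
    """Per-class Gaussian reflectance bands, truncated at 0.

    Each pixel's value in band *b* is drawn from
    N(mean[class][b], spread[class][b]) and clipped at 0; nodata pixels
    are masked.  The shipped defaults separate vegetation classes from
    built-up in NDVI expectation.
    """
    present = {landscape.legend.name_of(int(c)) for c in np.unique(landscape.grid[landscape.valid_mask])}
    missing = sorted(present - set(cfg.band_params))
    if missing:
        raise ConfigError(f"band parameters missing for classes: {missing}")
    band_names = sorted({b for per in cfg.band_params.values() for b in per}) or list(STANDARD_BANDS)

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    bands: dict[str, np.ndarray] = {}
    mask = ~landscape.valid_mask
    for band in band_names:
        out = np.zeros(landscape.shape, dtype=float)
        noise = rng.standard_normal(landscape.shape)
        for code, name in zip(landscape.legend.codes, landscape.legend.class_names):
            if name not in cfg.band_params:
                continue
            mean, spread = cfg.band_params[name].get(band, (0.0, 0.0))
            sel = landscape.grid == code
            out[sel] = mean + spread * noise[sel]
        bands[band] = np.clip(out, 0.0, None)
    return BandGrid(bands, mask=mask)
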