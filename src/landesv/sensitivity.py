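"""Coefficient-sensitivity (elasticity) analysis for benefit transfer.

Transferred value coefficients are uncertain, so the standard economic
elasticity is computed: adjust one biome's coefficient by a fraction
(±50% by default), revalue, and form

    CS = (ΔESV / ESV) ÷ (ΔVC / VC).

Because the valuation is linear in the coefficients, CS for a
single-biome adjustment equals that biome's share of the baseline total
ESV, independent of the adjustment's magnitude and sign; both +50% and
−50% are swept to make that explicit.  CS > 1 would mean the estimate is
elastic (fragile) with respect to that coefficient; CS < 1, inelastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .coefficients import ClassLegend, CoefficientTable
from .lulc import AreaTable
from .valuation import compute_esv

__all__ = [
    "SensitivityResult",
    "UndefinedElasticityError",
    "coefficient_sensitivity",
    "sensitivity_sweep",
    "sweep_frame",
]

logger = logging.getLogger(__name__)


class UndefinedElasticityError(ValueError):
    """CS is undefined (zero baseline coefficient or zero baseline ESV)."""


@dataclass(frozen=True)
class SensitivityResult:
    biome: str
    adjustment: float  # fraction, e.g. +0.5
    esv_baseline: float  # ESV_i, USD · yr⁻¹
    esv_adjusted: float  # ESV_j
    vc_baseline: float  # VC_ik
    vc_adjusted: float  # VC_jk
    cs: float

    @property
    def elastic(self) -> bool:
        return self.cs > 1.0


def coefficient_sensitivity(
    areas: AreaTable,
    coeffs: CoefficientTable,
    legend: ClassLegend,
    biome: str,
    adjustment: float,
) -> SensitivityResult:
    """Elasticity of total ESV with respect to one biome's coefficient.

    The adjustment is applied to the biome's total VC_k and,
    proportionally, to all its per-function cells, keeping the total- and
    function-based valuations consistent under the perturbation.
    """
    if adjustment == 0:
        raise ValueError("adjustment must be nonzero")
    vc_i = coeffs.vc(biome)
    if vc_i == 0:
        raise UndefinedElasticityError(
            f"biome {biome!r} has zero baseline coefficient; elasticity undefined"
        )
    esv_i = compute_esv(areas, coeffs, legend).total
    if esv_i == 0:
        raise UndefinedElasticityError("baseline total ESV is zero; elasticity undefined")
    adjusted = coeffs.scaled(biome, 1.0 + adjustment)
    esv_j = compute_esv(areas, adjusted, legend).total
    vc_j = adjusted.vc(biome)
    cs = ((esv_j - esv_i) / esv_i) / ((vc_j - vc_i) / vc_i)
    return SensitivityResult(biome, float(adjustment), esv_i, esv_j, vc_i, vc_j, cs)


def sensitivity_sweep(
    areas: AreaTable,
    coeffs: CoefficientTable,
    legend: ClassLegend,
    adjustments: tuple[float, ...] = (0.5, -0.5),
) -> list[SensitivityResult]:
    """One result per (valued biome × adjustment); zero-valued biomes skipped."""
    results = []
    for biome in coeffs.totals.index:
        if coeffs.vc(biome) == 0:
            logger.info("skipping biome %r: zero coefficient, elasticity undefined", biome)
            continue
        for adj in adjustments:
            results.append(coefficient_sensitivity(areas, coeffs, legend, biome, adj))
    return results


def sweep_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    """Tidy frame: biome,adjustment,esv_baseline,esv_adjusted,cs,elastic."""
    return pd.DataFrame(
        {
            "biome": [r.biome for r in results],
            "adjustment": [r.adjustment for r in results],
            "esv_baseline": [r.esv_baseline for r in results],
            "esv_adjusted": [r.esv_adjusted for r in results],
            "cs": [r.cs for r in results],
            "elastic": [r.elastic for r in results],
        }
    )
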