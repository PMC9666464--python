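"""Gross carbonate production from percent cover, traits, and rugosity.

For each calcifying taxon s the areal calcification rate is

    P_s = cover_s * extension_s * density_s * 10 * m(morphology_s) * R

in kg CaCO3 m^-2 yr^-1, where cover is a fraction of the planar transect,
extension is linear growth in cm yr^-1, density is skeletal density in
g cm^-3, the factor 10 converts g cm^-2 yr^-1 over one square meter to
kg m^-2 yr^-1, m(.) is a morphology conversion factor and R is the site
rugosity that converts the planar survey to true reef surface.  Gross
production is the sum over corals, CCA and other calcareous encrusters.

By default every morphology factor is 1: site rugosity measured from the
DEM already carries the topographic complexity that per-colony geometry
would otherwise add, and the factors stay exposed in ``BudgetConfig`` for
users who want branching taxa amplified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .survey_io import CodeMap, CoralTrait, SurveyError

__all__ = ["BudgetConfig", "ProductionBreakdown", "coral_production",
           "encruster_production", "gross_production"]

#: converts cover (fraction) x cm yr^-1 x g cm^-3 to kg CaCO3 m^-2 yr^-1
_KG_CONVERSION = 10.0

DEFAULT_MORPHOLOGY_FACTORS = {
    "encrusting_plating": 1.0,
    "massive": 1.0,
    "sub_massive": 1.0,
    "branching": 1.0,
}


@dataclass
class BudgetConfig:
    """Toggles shared by the production and erosion stages.

    ``rugosity_scaling`` controls which terms are multiplied by site
    rugosity: production and the area-based erosion terms (micro/macro
    borers, urchins) describe processes on the true reef surface measured
    by a planar transect, so they scale; the fish census counts fish over
    a planar cylinder, so parrotfish erosion does not.
    """

    morphology_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY_FACTORS))
    rugosity_scaling: dict[str, bool] = field(
        default_factory=lambda: {"production": True, "area_erosion": True,
                                 "census_erosion": False})


@dataclass
class ProductionBreakdown:
    """Per-taxon and total gross production, kg CaCO3 m^-2 yr^-1."""

    per_taxon: dict[str, float] = field(default_factory=dict)
    coral_total: float = 0.0
    cca_total: float = 0.0
    other_encruster_total: float = 0.0

    @property
    def gross_production(self) -> float:
        return self.coral_total + self.cca_total + self.other_encruster_total


def _taxon_rate(cover: float, trait: CoralTrait, rug: float,
                config: BudgetConfig) -> float:
    if cover < 0:
        raise SurveyError(f"negative cover for {trait.species_code}")
    if not trait.calcifier:
        return 0.0
    m = config.morphology_factors[trait.morphology]
    return cover * trait.extension_cm_yr * trait.density_g_cm3 * _KG_CONVERSION * m * rug


def coral_production(cover: Mapping[str, float], traits: Mapping[str, CoralTrait],
                     code_map: CodeMap, rugosity: float,
                     config: BudgetConfig | None = None) -> ProductionBreakdown:
    """Scleractinian production per species; fails on missing trait rows."""
    config = config or BudgetConfig()
    rug = rugosity if config.rugosity_scaling["production"] else 1.0
    out = ProductionBreakdown()
    for code, frac in cover.items():
        if not code_map.is_coral(code):
            continue
        if code not in traits:
            raise SurveyError(f"no trait row for coral species {code!r}")
        p = _taxon_rate(frac, traits[code], rug, config)
        out.per_taxon[code] = p
        out.coral_total += p
    return out


def encruster_production(cover: Mapping[str, float], traits: Mapping[str, CoralTrait],
                         code_map: CodeMap, rugosity: float,
                         config: BudgetConfig | None = None) -> ProductionBreakdown:
    """CCA and other calcareous encruster production (encrusting geometry).

    Covers every functional-group code flagged ``calcifier`` in the code
    map; a code flagged non-calcifier in the trait table contributes 0.
    """
    config = config or BudgetConfig()
    rug = rugosity if config.rugosity_scaling["production"] else 1.0
    out = ProductionBreakdown()
    for code in sorted(code_map.codes_with_flag("calcifier")):
        frac = cover.get(code, 0.0)
        if frac == 0.0:
            continue
        if code not in traits:
            raise SurveyError(f"no trait row for calcifying encruster {code!r}")
        p = _taxon_rate(frac, traits[code], rug, config)
        out.per_taxon[code] = p
        if code == "CCA":
            out.cca_total += p
        else:
            out.other_encruster_total += p
    return out


def gross_production(cover: Mapping[str, float], traits: Mapping[str, CoralTrait],
                     code_map: CodeMap, rugosity: float,
                     config: BudgetConfig | None = None) -> ProductionBreakdown:
    """Total gross carbonate production: corals plus calcareous encrusters."""
    config = config or BudgetConfig()
    corals = coral_production(cover, traits, code_map, rugosity, config)
    encr = encruster_production(cover, traits, code_map, rugosity, config)
    out = ProductionBreakdown(
        per_taxon={**corals.per_taxon, **encr.per_taxon},
        coral_total=corals.coral_total,
        cca_total=encr.cca_total,
        other_encruster_total=encr.other_encruster_total,
    )
    return out
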