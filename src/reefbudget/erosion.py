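"""Gross carbonate erosion: parrotfish, microborers, macroborers, urchins.

All four guild terms are stored positive (kg CaCO3 m^-2 yr^-1) and applied
as losses at budget assembly; reports print them with a leading minus.

Parrotfish erosion integrates the size-frequency census: each fish removes

    bite_rate [bites min^-1] * foraging minutes yr^-1 * bite_volume [cm^3]
    * scar_proportion * substrate_density [g cm^-3]

grams of framework per year; the site rate is the count-weighted sum over
species and 10 cm size bins divided by the census cylinder area.  Microboring
scales the literature rate 0.240 kg m^-2 yr^-1 by the cover of dead coral
substrate; macroboring scales the mean Caribbean clionid-sponge rate
6.05 kg m^-2 yr^-1 by clionid cover; urchin erosion multiplies Diadema
density by the rate of a mean-test-size (66 mm) individual, 0.003 kg yr^-1.
The cover-driven (area-based) terms are multiplied by site rugosity when
``rugosity_scaling['area_erosion']`` is on; the fish term is census-based
and planar by construction, so it is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .production import BudgetConfig
from .survey_io import CodeMap, EroderConstants, FishSurvey, ParrotfishParams, SurveyError

__all__ = ["ErosionBreakdown", "parrotfish_erosion", "microbioerosion",
           "macrobioerosion", "urchin_erosion", "gross_erosion"]


@dataclass
class ErosionBreakdown:
    """Per-guild erosion, kg CaCO3 m^-2 yr^-1, each stored positive."""

    parrotfish: float = 0.0
    microborer: float = 0.0
    macroborer: float = 0.0
    urchin: float = 0.0

    @property
    def gross_erosion(self) -> float:
        return self.parrotfish + self.microborer + self.macroborer + self.urchin

    @property
    def parrotfish_fraction(self) -> float:
        total = self.gross_erosion
        return self.parrotfish / total if total > 0 else 0.0


def parrotfish_erosion(survey: FishSurvey, params: ParrotfishParams,
                       constants: EroderConstants | None = None,
                       rugosity: float = 1.0,
                       config: BudgetConfig | None = None) -> float:
    """Site parrotfish erosion, kg CaCO3 m^-2 yr^-1."""
    constants = constants or EroderConstants()
    config = config or BudgetConfig()
    gone = params.missing(survey)
    if gone:
        raise SurveyError(f"no grazing parameters for {gone}")
    total_kg = 0.0
    for sp, (lo, _hi), count in survey.observations:
        p = params.lookup(sp, lo)
        grams_yr = (p["bite_rate_bites_min"] * constants.foraging_minutes_per_year
                    * p["bite_volume_cm3"] * p["scar_proportion"]
                    * constants.substrate_density_g_cm3)
        total_kg += count * grams_yr / 1000.0
    rate = total_kg / survey.survey_area_m2
    if config.rugosity_scaling["census_erosion"]:
        rate *= rugosity
    return rate


def _area_scale(rugosity: float, config: BudgetConfig) -> float:
    return rugosity if config.rugosity_scaling["area_erosion"] else 1.0


def microbioerosion(cover: Mapping[str, float], code_map: CodeMap,
                    constants: EroderConstants | None = None,
                    rugosity: float = 1.0,
                    config: BudgetConfig | None = None) -> float:
    """Endolithic microboring over the dead-coral-substrate cover."""
    constants = constants or EroderConstants()
    config = config or BudgetConfig()
    dead = sum(cover.get(c, 0.0) for c in code_map.codes_with_flag("dead_substrate"))
    if not 0.0 <= dead <= 1.0:
        raise SurveyError(f"dead substrate cover {dead} outside [0, 1]")
    return dead * constants.microborer_rate_kg_m2_yr * _area_scale(rugosity, config)


def macrobioerosion(cover: Mapping[str, float], code_map: CodeMap,
                    constants: EroderConstants | None = None,
                    rugosity: float = 1.0,
                    config: BudgetConfig | None = None) -> float:
    """Clionid-sponge macroboring over the clionid cover."""
    constants = constants or EroderConstants()
    config = config or BudgetConfig()
    clionid = sum(cover.get(c, 0.0) for c in code_map.codes_with_flag("clionid"))
    return clionid * constants.clionid_rate_kg_m2_yr * _area_scale(rugosity, config)


def urchin_erosion(urchin_count: int, survey_area_m2: float | None = None,
                   constants: EroderConstants | None = None,
                   rugosity: float = 1.0,
                   config: BudgetConfig | None = None) -> float:
    """Diadema erosion from abundance at the mean-test-size rate."""
    constants = constants or EroderConstants()
    config = config or BudgetConfig()
    if urchin_count < 0:
        raise SurveyError("negative urchin count")
    area = survey_area_m2 if survey_area_m2 is not None else constants.urchin_survey_area_m2
    density = urchin_count / area
    return density * constants.diadema_rate_kg_urchin_yr * _area_scale(rugosity, config)


def gross_erosion(cover: Mapping[str, float], fish: FishSurvey,
                  urchin_count: int, params: ParrotfishParams,
                  code_map: CodeMap, constants: EroderConstants | None = None,
                  rugosity: float = 1.0,
                  config: BudgetConfig | None = None) -> ErosionBreakdown:
    """All four guild terms for one site."""
    constants = constants or EroderConstants()
    config = config or BudgetConfig()
    return ErosionBreakdown(
        parrotfish=parrotfish_erosion(fish, params, constants, rugosity, config),
        microborer=microbioerosion(cover, code_map, constants, rugosity, config),
        macroborer=macrobioerosion(cover, code_map, constants, rugosity, config),
        urchin=urchin_erosion(urchin_count, None, constants, rugosity, config),
    )
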