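"""Survey data model and readers for benthic, fish, and parameter tables.

The benthic survey is a line point-intercept transect: a 15 m line sampled at
15 cm intervals gives 100 equidistant points, each coded either to a coral
species or to a benthic functional group (CCA, turf, macroalgae, ...).
Percent cover is the point-count fraction.  The fish survey follows a
stationary-cylinder visual census: parrotfish are recorded by species and
10 cm size bin over two 15 m diameter cylinders.  Urchin (Diadema) counts
ride along the benthic transect.

All trait and rate parameters live in plain CSV/YAML tables so that every
constant the budget equations consume is visible and overridable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "REGIONS",
    "SUBREGIONS",
    "REEF_TYPES",
    "N_TRANSECT_POINTS",
    "DEFAULT_SURVEY_AREA_M2",
    "SiteRecord",
    "BenthicSurvey",
    "FishSurvey",
    "CoralTrait",
    "ParrotfishParams",
    "EroderConstants",
    "CodeMap",
    "load_code_map",
    "load_coral_traits",
    "load_parrotfish_params",
    "load_eroder_constants",
    "read_benthic_table",
    "write_benthic_table",
    "percent_cover",
    "parrotfish_biomass",
    "read_fish_table",
    "write_fish_table",
]

REGIONS = ("DRTO", "FLK", "SEFL")
SUBREGIONS = ("DRTO", "LK", "MK", "UK", "BISC", "SEFL")
REEF_TYPES = ("bank", "forereef", "lagoon", "inshore", "mid_channel", "offshore", "none")

#: sub-regions belonging to each region
_REGION_SUBREGIONS = {
    "DRTO": ("DRTO",),
    "FLK": ("LK", "MK", "UK", "BISC"),
    "SEFL": ("SEFL",),
}
#: reef types valid in each region (no reef-type data exists for SEFL)
_REGION_REEF_TYPES = {
    "DRTO": ("bank", "forereef", "lagoon"),
    "FLK": ("inshore", "mid_channel", "offshore"),
    "SEFL": ("none",),
}

N_TRANSECT_POINTS = 100
#: two 15 m diameter point-count cylinders
DEFAULT_SURVEY_AREA_M2 = 2.0 * math.pi * 7.5**2


class SurveyError(ValueError):
    """Raised for malformed or inconsistent survey inputs."""


@dataclass(frozen=True)
class SiteRecord:
    """Identity and stratification of one survey site."""

    site_id: str
    region: str
    subregion: str
    reef_type: str
    lat: float
    lon: float
    year: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SurveyError(f"{self.site_id}: unknown region {self.region!r}")
        if self.subregion not in _REGION_SUBREGIONS[self.region]:
            raise SurveyError(
                f"{self.site_id}: subregion {self.subregion!r} inconsistent "
                f"with region {self.region!r}"
            )
        if self.reef_type not in _REGION_REEF_TYPES[self.region]:
            raise SurveyError(
                f"{self.site_id}: reef type {self.reef_type!r} invalid "
                f"for region {self.region!r}"
            )


@dataclass
class BenthicSurvey:
    """One site's 100-point transect plus the urchin count."""

    site: SiteRecord
    point_codes: tuple[str, ...]
    urchin_count: int = 0

    def __post_init__(self) -> None:
        self.point_codes = tuple(self.point_codes)
        if len(self.point_codes) != N_TRANSECT_POINTS:
            raise SurveyError(
                f"{self.site.site_id}: expected {N_TRANSECT_POINTS} transect "
                f"points, got {len(self.point_codes)}"
            )
        if self.urchin_count < 0:
            raise SurveyError(f"{self.site.site_id}: negative urchin count")


@dataclass
class FishSurvey:
    """Parrotfish size-frequency observations for one site.

    ``observations`` is a list of ``(species_code, (bin_lo, bin_hi), count)``
    with 10 cm wide fork-length bins.
    """

    site: SiteRecord
    observations: list[tuple[str, tuple[float, float], int]] = field(default_factory=list)
    survey_area_m2: float = DEFAULT_SURVEY_AREA_M2

    def __post_init__(self) -> None:
        if self.survey_area_m2 <= 0:
            raise SurveyError(f"{self.site.site_id}: non-positive survey area")
        for sp, (lo, hi), count in self.observations:
            if count < 0:
                raise SurveyError(f"{self.site.site_id}: negative count for {sp}")
            if not math.isclose(hi - lo, 10.0):
                raise SurveyError(
                    f"{self.site.site_id}: size bin [{lo},{hi}) is not 10 cm wide"
                )


@dataclass(frozen=True)
class CoralTrait:
    """Per-species calcification traits."""

    species_code: str
    morphology: str
    extension_cm_yr: float
    density_g_cm3: float
    calcifier: bool = True

    _MORPHOLOGIES = ("branching", "massive", "sub_massive", "encrusting_plating")

    def __post_init__(self) -> None:
        if self.morphology not in self._MORPHOLOGIES:
            raise SurveyError(f"{self.species_code}: unknown morphology {self.morphology!r}")
        if not 0 < self.density_g_cm3 <= 3:
            raise SurveyError(f"{self.species_code}: density out of (0, 3]")
        if self.extension_cm_yr <= 0:
            raise SurveyError(f"{self.species_code}: non-positive extension rate")


@dataclass(frozen=True)
class ParrotfishParams:
    """Species x size-bin grazing and length-weight parameters.

    ``bins`` maps ``(species_code, bin_lo)`` to a dict with keys
    ``bite_rate_bites_min``, ``bite_volume_cm3``, ``scar_proportion``,
    ``lw_a``, ``lw_b``.  Weight follows W = a * L**b in grams with fork
    length L in cm.
    """

    bins: Mapping[tuple[str, float], dict]

    def lookup(self, species_code: str, bin_lo: float) -> dict:
        try:
            return self.bins[(species_code, float(bin_lo))]
        except KeyError:
            raise SurveyError(
                f"no parrotfish parameters for {species_code} bin starting {bin_lo}"
            ) from None

    def missing(self, survey: FishSurvey) -> list[str]:
        gone = sorted(
            {
                f"{sp}:{lo:g}"
                for sp, (lo, _hi), _c in survey.observations
                if (sp, float(lo)) not in self.bins
            }
        )
        return gone


@dataclass(frozen=True)
class EroderConstants:
    """Fixed bioeroder rate constants; stored positive, applied as losses."""

    substrate_density_g_cm3: float = 1.72
    microborer_rate_kg_m2_yr: float = 0.240
    clionid_rate_kg_m2_yr: float = 6.05
    diadema_rate_kg_urchin_yr: float = 0.003
    foraging_minutes_per_year: float = 131400.0
    urchin_survey_area_m2: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "substrate_density_g_cm3",
            "microborer_rate_kg_m2_yr",
            "clionid_rate_kg_m2_yr",
            "diadema_rate_kg_urchin_yr",
            "foraging_minutes_per_year",
            "urchin_survey_area_m2",
        ):
            if getattr(self, name) <= 0:
                raise SurveyError(f"EroderConstants.{name} must be positive")


@dataclass(frozen=True)
class CodeMap:
    """Closed vocabulary of benthic codes and their role flags."""

    groups: Mapping[str, dict]
    coral_species: frozenset[str]

    def is_known(self, code: str) -> bool:
        return code in self.groups or code in self.coral_species

    def is_coral(self, code: str) -> bool:
        return code in self.coral_species

    def codes_with_flag(self, flag: str) -> frozenset[str]:
        return frozenset(c for c, f in self.groups.items() if f.get(flag, False))


def _data_path(name: str):
    return resources.files("reefbudget.data").joinpath(name)


def load_code_map(path: str | Path | None = None,
                  coral_species: Iterable[str] | None = None) -> CodeMap:
    """Load the benthic code vocabulary (YAML); defaults to the shipped map.

    ``coral_species`` defaults to the species in the shipped trait table.
    """
    src = Path(path).read_text() if path is not None else _data_path("benthic_codes.yml").read_text()
    doc = yaml.safe_load(src)
    if coral_species is None:
        traits = load_coral_traits()
        coral_species = [c for c, t in traits.items() if c not in doc["groups"]]
    return CodeMap(groups=doc["groups"], coral_species=frozenset(coral_species))


def load_coral_traits(path: str | Path | None = None) -> dict[str, CoralTrait]:
    """Load the coral/encruster trait table (CSV keyed by species_code)."""
    src = path if path is not None else _data_path("coral_traits.csv")
    df = pd.read_csv(src)
    out: dict[str, CoralTrait] = {}
    for row in df.itertuples(index=False):
        out[row.species_code] = CoralTrait(
            species_code=row.species_code,
            morphology=row.morphology,
            extension_cm_yr=float(row.extension_cm_yr),
            density_g_cm3=float(row.density_g_cm3),
            calcifier=str(row.calcifier).strip().lower() in ("true", "1", "yes"),
        )
    return out


def load_parrotfish_params(path: str | Path | None = None) -> ParrotfishParams:
    """Load the parrotfish species x size-bin parameter table (CSV)."""
    src = path if path is not None else _data_path("parrotfish_params.csv")
    df = pd.read_csv(src)
    bins: dict[tuple[str, float], dict] = {}
    for row in df.itertuples(index=False):
        if not 0 <= row.scar_proportion <= 1:
            raise SurveyError(f"{row.species_code}: scar proportion outside [0,1]")
        bins[(row.species_code, float(row.bin_lo_cm))] = {
            "bin_hi_cm": float(row.bin_hi_cm),
            "bite_rate_bites_min": float(row.bite_rate_bites_min),
            "bite_volume_cm3": float(row.bite_volume_cm3),
            "scar_proportion": float(row.scar_proportion),
            "lw_a": float(row.lw_a),
            "lw_b": float(row.lw_b),
        }
    # bite volume must not shrink as fish grow
    for sp in {k[0] for k in bins}:
        vols = [bins[k]["bite_volume_cm3"] for k in sorted(bins) if k[0] == sp]
        if any(b < a for a, b in zip(vols, vols[1:])):
            raise SurveyError(f"{sp}: bite volume decreases with size bin")
    return ParrotfishParams(bins=bins)


def load_eroder_constants(path: str | Path | None = None) -> EroderConstants:
    """Load eroder rate constants from YAML; defaults to the shipped values."""
    src = Path(path).read_text() if path is not None else _data_path("eroder_constants.yml").read_text()
    doc = yaml.safe_load(src)
    return EroderConstants(**doc)


# ---------------------------------------------------------------------------
# site metadata helpers

_SITE_COLUMNS = ["site_id", "region", "subregion", "reef_type", "lat", "lon", "year"]


def _site_from_row(row: Mapping) -> SiteRecord:
    missing = [c for c in _SITE_COLUMNS if c not in row or pd.isna(row[c])]
    if missing:
        raise SurveyError(f"site metadata missing columns {missing}")
    return SiteRecord(
        site_id=str(row["site_id"]),
        region=str(row["region"]),
        subregion=str(row["subregion"]),
        reef_type=str(row["reef_type"]),
        lat=float(row["lat"]),
        lon=float(row["lon"]),
        year=int(row["year"]),
    )


# ---------------------------------------------------------------------------
# benthic table IO

def read_benthic_table(
    path: str | Path,
    dialect: str,
    code_map: CodeMap | None = None,
    urchin_column: str = "urchin_count",
) -> list[BenthicSurvey]:
    """Read a benthic survey table in one of two explicit dialects.

    ``dialect='points'``: one row per transect point with columns
    ``site_id, region, subregion, reef_type, lat, lon, year, point_index,
    code`` (plus an optional per-site urchin count column).  ``dialect=
    'summary'`` is one row per site with one ``cover_<code>`` column per
    benthic code holding fractions that must sum to 1 within 1e-6; point
    codes are reconstructed as ``round(fraction * 100)`` points per code
    (requiring the fractions to be multiples of 0.01).

    The dialect is never sniffed.  Unknown codes are rejected.
    """
    if dialect not in ("points", "summary"):
        raise SurveyError(f"unknown benthic dialect {dialect!r}")
    cm = code_map or load_code_map()
    df = pd.read_csv(path)
    surveys: list[BenthicSurvey] = []

    if dialect == "points":
        for site_id, grp in df.groupby("site_id", sort=False):
            site = _site_from_row(grp.iloc[0])
            grp = grp.sort_values("point_index")
            codes = [str(c) for c in grp["code"]]
            bad = sorted({c for c in codes if not cm.is_known(c)})
            if bad:
                raise SurveyError(f"{site_id}: unknown benthic codes {bad}")
            urchins = int(grp[urchin_column].iloc[0]) if urchin_column in grp else 0
            surveys.append(BenthicSurvey(site=site, point_codes=tuple(codes),
                                         urchin_count=urchins))
        return surveys

    cover_cols = [c for c in df.columns if c.startswith("cover_")]
    for _, row in df.iterrows():
        site = _site_from_row(row)
        covers = {c[len("cover_"):]: float(row[c]) for c in cover_cols if row[c] > 0}
        bad = sorted({c for c in covers if not cm.is_known(c)})
        if bad:
            raise SurveyError(f"{site.site_id}: unknown benthic codes {bad}")
        total = sum(covers.values())
        if abs(total - 1.0) > 1e-6:
            raise SurveyError(
                f"{site.site_id}: cover fractions sum to {total:.6f}, not 1"
            )
        codes: list[str] = []
        for code in sorted(covers):
            n = round(covers[code] * N_TRANSECT_POINTS)
            if abs(n - covers[code] * N_TRANSECT_POINTS) > 1e-6:
                raise SurveyError(
                    f"{site.site_id}: cover {covers[code]} for {code} is not a "
                    f"multiple of 1/{N_TRANSECT_POINTS}"
                )
            codes.extend([code] * n)
        urchins = int(row[urchin_column]) if urchin_column in row and not pd.isna(row[urchin_column]) else 0
        surveys.append(BenthicSurvey(site=site, point_codes=tuple(codes),
                                     urchin_count=urchins))
    return surveys


def write_benthic_table(surveys: Sequence[BenthicSurvey], path: str | Path) -> None:
    """Write surveys in the point-level dialect as RFC-4180 CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SITE_COLUMNS + ["point_index", "code", "urchin_count"])
        for s in surveys:
            meta = [s.site.site_id, s.site.region, s.site.subregion,
                    s.site.reef_type, s.site.lat, s.site.lon, s.site.year]
            for i, code in enumerate(s.point_codes):
                w.writerow(meta + [i, code, s.urchin_count])


def percent_cover(survey: BenthicSurvey) -> dict[str, float]:
    """Cover fraction per code: exact point count / 100; fractions sum to 1."""
    counts: dict[str, int] = {}
    for code in survey.point_codes:
        counts[code] = counts.get(code, 0) + 1
    return {code: n / N_TRANSECT_POINTS for code, n in sorted(counts.items())}


# ---------------------------------------------------------------------------
# fish table IO and biomass

def read_fish_table(path: str | Path,
                    survey_area_m2: float = DEFAULT_SURVEY_AREA_M2) -> list[FishSurvey]:
    """Read a fish survey CSV: one row per (site, species, size bin).

    Columns: site metadata plus ``species_code, bin_lo_cm, bin_hi_cm, count``.
    Sites with zero parrotfish may appear as a single row with empty species
    and count 0.
    """
    df = pd.read_csv(path)
    surveys: list[FishSurvey] = []
    for site_id, grp in df.groupby("site_id", sort=False):
        site = _site_from_row(grp.iloc[0])
        obs = []
        for row in grp.itertuples(index=False):
            if pd.isna(row.species_code) or row.count == 0:
                continue
            obs.append((str(row.species_code),
                        (float(row.bin_lo_cm), float(row.bin_hi_cm)),
                        int(row.count)))
        area = float(grp["survey_area_m2"].iloc[0]) if "survey_area_m2" in grp else survey_area_m2
        surveys.append(FishSurvey(site=site, observations=obs, survey_area_m2=area))
    return surveys


def write_fish_table(surveys: Sequence[FishSurvey], path: str | Path) -> None:
    """Write fish surveys as RFC-4180 CSV (one row per species x bin)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SITE_COLUMNS + ["species_code", "bin_lo_cm", "bin_hi_cm",
                                    "count", "survey_area_m2"])
        for s in surveys:
            meta = [s.site.site_id, s.site.region, s.site.subregion,
                    s.site.reef_type, s.site.lat, s.site.lon, s.site.year]
            if not s.observations:
                w.writerow(meta + ["", "", "", 0, s.survey_area_m2])
            for sp, (lo, hi), count in s.observations:
                w.writerow(meta + [sp, lo, hi, count, s.survey_area_m2])


def parrotfish_biomass(survey: FishSurvey, params: ParrotfishParams) -> float:
    """Parrotfish biomass in kg per hectare.

    Each fish is assigned the weight of its size-bin midpoint via the
    species length-weight power law W = a * L**b (grams), summed over the
    census and standardized by the survey area.
    """
    gone = params.missing(survey)
    if gone:
        raise SurveyError(f"no length-weight parameters for {gone}")
    grams = 0.0
    for sp, (lo, hi), count in survey.observations:
        p = params.lookup(sp, lo)
        mid = (lo + hi) / 2.0
        grams += count * p["lw_a"] * mid ** p["lw_b"]
    kg_m2 = grams / 1000.0 / survey.survey_area_m2
    return kg_m2 * 1e4
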