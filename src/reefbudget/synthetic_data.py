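"""Synthetic survey generator emulating the stratified Florida Reef Tract design.

The generator reproduces the statistical skeleton of the monitoring design
the budget pipeline expects: 723 sites split over three biogeographic
regions — Dry Tortugas (DRTO, n=228), Florida Keys (FLK, n=322: Lower Keys
103, Middle Keys 46, Upper Keys 140, Biscayne 33) and Southeast Florida
(SEFL, n=173) — with reef types nested in each region (DRTO: bank /
forereef / lagoon; Keys sub-regions: inshore / mid-channel / offshore;
SEFL: none).  Per-stratum benthic cover is drawn from truncated normals
around published regional means (SD recovered from the reported standard
errors as SE * sqrt(n)), renormalized onto the simplex with an iterative
mean-compensation step, then realized as a 100-point multinomial transect.
Coral cover is split over a small species list by a fixed-weight Dirichlet.
Parrotfish biomass is lognormal per region (mean/SD targets from the
regional census summaries) and realized as Poisson counts over a fixed
species x size-bin biomass composition.  Per-site DEMs are smoothed
Gaussian random fields whose amplitude varies by reef type.

Everything is deterministic under the seed.  The known-truth scenarios
construct fixtures whose budgets are analytically known site-by-site, for
oracle and parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .rugosity import DemGrid, write_esri_ascii
from .survey_io import (
    DEFAULT_SURVEY_AREA_M2,
    N_TRANSECT_POINTS,
    BenthicSurvey,
    EroderConstants,
    FishSurvey,
    SiteRecord,
    load_parrotfish_params,
    write_benthic_table,
    write_fish_table,
)

__all__ = ["FixtureConfig", "SiteBundle", "generate_fixture", "write_fixture",
           "draw_cover_vectors", "generate_known_truth", "SCENARIOS"]

#: benthic categories carried by the stratum cover tables (percent mean, SE);
#: sand takes the remainder of the mean with a nominal 1% SE.
_COVER_CATEGORIES = ("coral", "CCA", "hydrocoral", "macroalgae", "soft_coral",
                     "sponge", "seagrass", "turf", "bare", "sand")

#: per sub-region {category: (mean %, SE %)} from the regional survey summaries
_COVER_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "DRTO": {"coral": (7.8, 0.5), "CCA": (2.6, 0.2), "hydrocoral": (0.9, 0.1),
             "macroalgae": (41.3, 1.2), "soft_coral": (7.3, 0.4),
             "sponge": (6.3, 0.3), "seagrass": (0.1, 0.1), "turf": (15.6, 1.0),
             "bare": (14.6, 1.0)},
    "LK":   {"coral": (10.7, 1.1), "CCA": (5.1, 0.6), "hydrocoral": (0.8, 0.1),
             "macroalgae": (17.4, 1.6), "soft_coral": (5.7, 0.4),
             "sponge": (7.4, 0.7), "seagrass": (0.2, 0.2), "turf": (30.7, 1.6),
             "bare": (18.6, 1.5)},
    "MK":   {"coral": (9.6, 1.5), "CCA": (3.7, 0.7), "hydrocoral": (0.8, 0.1),
             "macroalgae": (20.1, 2.6), "soft_coral": (3.2, 0.7),
             "sponge": (7.7, 0.7), "seagrass": (0.0, 0.0), "turf": (30.3, 2.6),
             "bare": (23.7, 2.9)},
    "UK":   {"coral": (7.3, 0.8), "CCA": (4.2, 0.4), "hydrocoral": (1.2, 0.1),
             "macroalgae": (27.3, 1.2), "soft_coral": (3.6, 0.3),
             "sponge": (4.3, 0.3), "seagrass": (1.5, 0.5), "turf": (32.2, 1.4),
             "bare": (17.8, 1.4)},
    "BISC": {"coral": (5.4, 0.9), "CCA": (2.3, 0.5), "hydrocoral": (0.9, 0.2),
             "macroalgae": (22.2, 3.0), "soft_coral": (9.5, 1.7),
             "sponge": (6.9, 1.1), "seagrass": (0.8, 0.5), "turf": (40.3, 4.2),
             "bare": (8.8, 2.3)},
    "SEFL": {"coral": (1.5, 0.2), "CCA": (1.1, 0.2), "hydrocoral": (0.3, 0.05),
             "macroalgae": (23.8, 1.4), "soft_coral": (8.9, 0.7),
             "sponge": (9.7, 0.6), "seagrass": (0.4, 0.2), "turf": (38.4, 1.6),
             "bare": (11.2, 1.3)},
}

_SUBREGION_REGION = {"DRTO": "DRTO", "LK": "FLK", "MK": "FLK", "UK": "FLK",
                     "BISC": "FLK", "SEFL": "SEFL"}
_SUBREGION_REEF_TYPES = {
    "DRTO": ("bank", "forereef", "lagoon"),
    "LK": ("inshore", "mid_channel", "offshore"),
    "MK": ("inshore", "mid_channel", "offshore"),
    "UK": ("inshore", "mid_channel", "offshore"),
    "BISC": ("inshore", "mid_channel", "offshore"),
    "SEFL": ("none",),
}

#: regional parrotfish biomass targets, kg ha^-1 (mean, SD)
_BIOMASS_TABLE = {"DRTO": (48.4, 40.2), "FLK": (118.7, 160.9), "SEFL": (57.1, 93.2)}

#: fixed coral species weights within total coral cover (Dirichlet base)
_CORAL_WEIGHTS = {"PAST": 0.35, "SSID": 0.35, "OFAV": 0.08, "MCAV": 0.15,
                  "PPOR": 0.05, "ACER": 0.02}

#: share of sponge cover contributed by excavating clionid sponges
_CLIONID_FRACTION = 0.10

#: biomass fractions over (species, bin_lo) classes in the fish census
_FISH_COMPOSITION = {
    ("SCA_ISE", 0.0): 0.03, ("SCA_ISE", 10.0): 0.12, ("SCA_ISE", 20.0): 0.10,
    ("SPA_AUR", 10.0): 0.15, ("SPA_AUR", 20.0): 0.10,
    ("SPA_VIR", 10.0): 0.15, ("SPA_VIR", 20.0): 0.15, ("SPA_VIR", 30.0): 0.05,
    ("SCA_VET", 10.0): 0.08, ("SCA_VET", 20.0): 0.07,
}

#: DEM relief amplitude (m) by reef type, before spatial smoothing
_DEM_AMPLITUDE = {"bank": 5.5, "forereef": 5.5, "lagoon": 3.0, "inshore": 2.5,
                  "mid_channel": 4.0, "offshore": 5.5, "none": 2.0}

_YEARS = (2014, 2016, 2018)
_DEM_N = 19          # cells per side at 1 m; ROI clips a 15 m square
_DEM_SMOOTH_SIGMA = 1.5


@dataclass
class FixtureConfig:
    """Stratified design of the synthetic survey campaign."""

    site_counts: dict[str, int] = field(default_factory=lambda: {
        "DRTO": 228, "LK": 103, "MK": 46, "UK": 140, "BISC": 33, "SEFL": 173})
    cover_table: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _COVER_TABLE.items()})
    biomass_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_BIOMASS_TABLE))
    coral_weights: dict[str, float] = field(default_factory=lambda: dict(_CORAL_WEIGHTS))
    clionid_fraction: float = _CLIONID_FRACTION
    fish_composition: dict[tuple[str, float], float] = field(
        default_factory=lambda: dict(_FISH_COMPOSITION))
    dem_amplitude: dict[str, float] = field(default_factory=lambda: dict(_DEM_AMPLITUDE))
    urchin_mean: float = 0.05
    sand_se: float = 1.0
    dirichlet_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.site_counts.values()):
            raise ValueError("site counts must be positive")
        if abs(sum(self.fish_composition.values()) - 1.0) > 1e-9:
            raise ValueError("fish composition fractions must sum to 1")


@dataclass
class SiteBundle:
    site: SiteRecord
    benthic: BenthicSurvey
    fish: FishSurvey
    dem: DemGrid
    dem_center: tuple[float, float]


def _stratum_moments(config: FixtureConfig, subregion: str) -> tuple[np.ndarray, np.ndarray]:
    """Target cover means and SDs (fractions) for the 10 categories + coral."""
    table = config.cover_table[subregion]
    n = config.site_counts[subregion]
    means, sds = [], []
    for cat in _COVER_CATEGORIES:
        if cat == "sand":
            m = max(0.0, 100.0 - sum(v[0] for v in table.values()))
            se = config.sand_se
        else:
            m, se = table[cat]
        if m < 0 or se < 0:
            raise ValueError(f"{subregion}/{cat}: negative cover mean or SE")
        means.append(m / 100.0)
        sds.append(se * math.sqrt(n) / 100.0)
    if sum(means) <= 0:
        raise ValueError(f"{subregion}: cover means sum to zero")
    return np.array(means), np.array(sds)


def _draw_simplex(rng: np.random.Generator, locs: np.ndarray, sds: np.ndarray,
                  n: int) -> np.ndarray:
    """Clipped-normal draws renormalized to the simplex, one row per site.

    ``locs`` are normal location parameters and may be negative: clipping at
    zero then maps them to small positive marginal means.
    """
    raw = rng.normal(locs, sds, size=(n, len(locs)))
    raw = np.clip(raw, 0.0, None)
    totals = raw.sum(axis=1)
    # a pathological draw could zero out; resample those rows from the means
    bad = totals <= 0
    if bad.any():
        raw[bad] = np.clip(locs, 1e-6, None)
        totals = raw.sum(axis=1)
    return raw / totals[:, None]


def _clipped_mean(loc: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """E[max(N(loc, sd), 0)] elementwise; exact for sd = 0 too."""
    from scipy.stats import norm
    loc = np.asarray(loc, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.maximum(loc, 0.0)
    pos = sd > 0
    a = loc[pos] / sd[pos]
    out = out.astype(float)
    out[pos] = loc[pos] * norm.cdf(a) + sd[pos] * norm.pdf(a)
    return out


def _solve_locs(targets: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Location parameters whose clipped means equal the targets.

    The clipped mean is strictly increasing in the location, so each
    category solves by bisection; unreachable zeros map far below zero.
    """
    from scipy.optimize import brentq
    locs = np.empty_like(targets)
    for k, (t, sd) in enumerate(zip(targets, sds)):
        if sd == 0:
            locs[k] = t
        elif t <= 0:
            locs[k] = -10.0 * sd
        else:
            f = lambda a: float(_clipped_mean(np.array([a]), np.array([sd]))[0]) - t
            lo, hi = t - 8 * sd, t + 8 * sd
            locs[k] = brentq(f, lo, hi, xtol=1e-12)
    return locs


_CAL_CACHE: dict[tuple, np.ndarray] = {}


def _calibrated_locs(means: np.ndarray, sds: np.ndarray, seed_key: int = 0,
                     n_cal: int = 20000, max_iter: int = 8) -> np.ndarray:
    """Compensate the mean shift induced by clipping + renormalization.

    Analytically matches the unnormalized clipped means to working targets,
    then polishes the targets with a few damped Monte Carlo corrections so
    the post-renormalization marginal means land on the requested ones.
    Uses a fixed internal stream so calibration is deterministic and
    cacheable independent of the caller's generator state.
    """
    key = (tuple(np.round(means, 12)), tuple(np.round(sds, 12)))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    cal_rng = np.random.default_rng(987654321 + seed_key)
    work = means.copy()
    locs = _solve_locs(work, sds)
    for _ in range(max_iter):
        realized = _draw_simplex(cal_rng, locs, sds, n_cal).mean(axis=0)
        err = np.abs(realized - means).max()
        if err < 5e-4:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(realized > 0, means / realized, 1.0)
        work = work * ratio ** 0.7
        locs = _solve_locs(work, sds)
    _CAL_CACHE[key] = locs
    return locs


def draw_cover_vectors(config: FixtureConfig, subregion: str, n: int,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site cover fractions (columns = categories) for one stratum."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    means, sds = _stratum_moments(config, subregion)
    locs = _calibrated_locs(means, sds)
    mat = _draw_simplex(rng, locs, sds, n)
    return pd.DataFrame(mat, columns=_COVER_CATEGORIES)


def _point_codes(rng: np.random.Generator, cover: pd.Series,
                 config: FixtureConfig) -> tuple[str, ...]:
    """Realize one 100-point transect from a site cover vector."""
    species = sorted(config.coral_weights)
    w = np.array([config.coral_weights[s] for s in species])
    split = rng.dirichlet(config.dirichlet_concentration * w)
    labels: list[str] = []
    probs: list[float] = []
    for cat in _COVER_CATEGORIES:
        frac = float(cover[cat])
        if frac <= 0:
            continue
        if cat == "coral":
            for s, ws in zip(species, split):
                labels.append(s)
                probs.append(frac * ws)
        elif cat == "sponge":
            labels.extend(["sponge", "clionid_sponge"])
            probs.extend([frac * (1 - config.clionid_fraction),
                          frac * config.clionid_fraction])
        else:
            labels.append(cat)
            probs.append(frac)
    p = np.array(probs)
    counts = rng.multinomial(N_TRANSECT_POINTS, p / p.sum())
    codes: list[str] = []
    for lab, c in zip(labels, counts):
        codes.extend([lab] * int(c))
    return tuple(codes)


def _fish_survey(rng: np.random.Generator, site: SiteRecord,
                 config: FixtureConfig, params) -> FishSurvey:
    """Poisson counts over the fixed composition hitting a lognormal biomass."""
    mean, sd = config.biomass_table[site.region]
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    target_kg_ha = rng.lognormal(mu, math.sqrt(sigma2))
    site_kg = target_kg_ha * DEFAULT_SURVEY_AREA_M2 / 1e4
    obs = []
    for (sp, lo), frac in sorted(config.fish_composition.items()):
        p = params.lookup(sp, lo)
        mid = (lo + p["bin_hi_cm"]) / 2.0
        w_kg = p["lw_a"] * mid ** p["lw_b"] / 1000.0
        lam = site_kg * frac / w_kg
        count = int(rng.poisson(lam))
        if count > 0:
            obs.append((sp, (lo, p["bin_hi_cm"]), count))
    return FishSurvey(site=site, observations=obs)


def _site_dem(rng: np.random.Generator, reef_type: str,
              config: FixtureConfig) -> tuple[DemGrid, tuple[float, float]]:
    amp = config.dem_amplitude[reef_type]
    z = rng.normal(0.0, amp, size=(_DEM_N, _DEM_N))
    z = ndimage.gaussian_filter(z, _DEM_SMOOTH_SIGMA, mode="reflect")
    z -= 20.0  # plausible depth; rugosity is invariant to the offset
    dem = DemGrid(elevations=z, cell_size_m=1.0, origin=(0.0, 0.0))
    return dem, (_DEM_N / 2.0, _DEM_N / 2.0)


def generate_fixture(config: FixtureConfig | None = None) -> list[SiteBundle]:
    """Generate the full synthetic campaign: one bundle per site.

    Deterministic under ``config.seed``; site counts follow the stratified
    design exactly, reef types rotate evenly within each stratum.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    params = load_parrotfish_params()
    bundles: list[SiteBundle] = []
    for subregion in sorted(config.site_counts):
        n = config.site_counts[subregion]
        region = _SUBREGION_REGION[subregion]
        reef_types = _SUBREGION_REEF_TYPES[subregion]
        covers = draw_cover_vectors(config, subregion, n, rng)
        for i in range(n):
            site = SiteRecord(
                site_id=f"{subregion}_{i:04d}",
                region=region,
                subregion=subregion,
                reef_type=reef_types[i % len(reef_types)],
                lat=24.5 + float(rng.uniform(0, 2.0)),
                lon=-82.9 + float(rng.uniform(0, 2.9)),
                year=int(_YEARS[int(rng.integers(len(_YEARS)))]),
            )
            codes = _point_codes(rng, covers.iloc[i], config)
            urchins = int(rng.poisson(config.urchin_mean))
            benthic = BenthicSurvey(site=site, point_codes=codes, urchin_count=urchins)
            fish = _fish_survey(rng, site, config, params)
            dem, center = _site_dem(rng, site.reef_type, config)
            bundles.append(SiteBundle(site=site, benthic=benthic, fish=fish,
                                      dem=dem, dem_center=center))
    return bundles


def write_fixture(bundles: Sequence[SiteBundle], outdir: str | Path) -> None:
    """Write benthic.csv, fish.csv, sites.csv and dems/<site_id>.asc."""
    out = Path(outdir)
    (out / "dems").mkdir(parents=True, exist_ok=True)
    write_benthic_table([b.benthic for b in bundles], out / "benthic.csv")
    write_fish_table([b.fish for b in bundles], out / "fish.csv")
    rows = []
    for b in bundles:
        s = b.site
        rows.append({"site_id": s.site_id, "region": s.region,
                     "subregion": s.subregion, "reef_type": s.reef_type,
                     "lat": s.lat, "lon": s.lon, "year": s.year,
                     "dem_center_x": b.dem_center[0], "dem_center_y": b.dem_center[1]})
        write_esri_ascii(b.dem, out / "dems" / f"{s.site_id}.asc")
    pd.DataFrame(rows).to_csv(out / "sites.csv", index=False)


# ---------------------------------------------------------------------------
# known-truth scenarios

SCENARIOS = ("all_zero", "only_microboring", "linear_cover_gradient")

#: gradient scenario knobs: one massive coral species against bare substrate,
#: response noise from Poisson parrotfish counts of one size class
_GRADIENT_SPECIES = "PAST"
_GRADIENT_EXT_DENS_10 = 0.31 * 1.42 * 10.0
_GRADIENT_FISH = ("SPA_VIR", (20.0, 30.0))
_GRADIENT_FISH_MEAN = 4.0
_GRADIENT_COVER_MAX = 0.40


def _truth_site(i: int) -> SiteRecord:
    return SiteRecord(site_id=f"T{i:04d}", region="DRTO", subregion="DRTO",
                      reef_type="bank", lat=24.6, lon=-82.8, year=2014)


def generate_known_truth(scenario: str, n_sites: int = 60,
                         seed: int = 0) -> tuple[list[SiteBundle], pd.DataFrame, dict]:
    """Fixture with analytically known budgets plus its truth ledger.

    Returns ``(bundles, ledger, truth)`` where the ledger holds the exact
    per-site gcp/gce/ncp computed by straight-line arithmetic from the
    generating constants (rugosity fixed at 1: every DEM is flat), and
    ``truth`` carries scenario-level parameters such as the regression
    slope/intercept/threshold for the cover-gradient design.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    constants = EroderConstants()
    params = load_parrotfish_params()
    flat = DemGrid(elevations=np.full((_DEM_N, _DEM_N), -20.0), cell_size_m=1.0)
    center = (_DEM_N / 2.0, _DEM_N / 2.0)

    sp, (blo, bhi) = _GRADIENT_FISH
    p = params.lookup(sp, blo)
    per_fish_kg_yr = (p["bite_rate_bites_min"] * constants.foraging_minutes_per_year
                      * p["bite_volume_cm3"] * p["scar_proportion"]
                      * constants.substrate_density_g_cm3 / 1000.0)
    per_fish_rate = per_fish_kg_yr / DEFAULT_SURVEY_AREA_M2

    bundles: list[SiteBundle] = []
    rows = []
    truth: dict = {"scenario": scenario}

    for i in range(n_sites):
        site = _truth_site(i)
        if scenario == "all_zero":
            codes = ("sand",) * N_TRANSECT_POINTS
            fish_obs: list = []
            gcp = gce = 0.0
        elif scenario == "only_microboring":
            codes = ("bare",) * N_TRANSECT_POINTS
            fish_obs = []
            gcp = 0.0
            gce = constants.microborer_rate_kg_m2_yr
        else:  # linear_cover_gradient
            c_true = float(rng.uniform(0.0, _GRADIENT_COVER_MAX))
            k = int(rng.binomial(N_TRANSECT_POINTS, c_true))
            codes = (_GRADIENT_SPECIES,) * k + ("bare",) * (N_TRANSECT_POINTS - k)
            c_hat = k / N_TRANSECT_POINTS
            n_fish = int(rng.poisson(_GRADIENT_FISH_MEAN))
            fish_obs = [(sp, (blo, bhi), n_fish)] if n_fish else []
            gcp = c_hat * _GRADIENT_EXT_DENS_10
            gce = (1.0 - c_hat) * constants.microborer_rate_kg_m2_yr + n_fish * per_fish_rate
        fish = FishSurvey(site=site, observations=fish_obs)
        benthic = BenthicSurvey(site=site, point_codes=codes, urchin_count=0)
        bundles.append(SiteBundle(site=site, benthic=benthic, fish=fish,
                                  dem=flat, dem_center=center))
        rows.append({"site_id": site.site_id, "gcp": gcp, "gce": gce,
                     "ncp": gcp - gce})

    if scenario == "linear_cover_gradient":
        slope_pct = (_GRADIENT_EXT_DENS_10 + constants.microborer_rate_kg_m2_yr) / 100.0
        intercept = -(constants.microborer_rate_kg_m2_yr
                      + _GRADIENT_FISH_MEAN * per_fish_rate)
        truth.update({
            "slope_per_pct": slope_pct,
            "intercept": intercept,
            "threshold_pct": -intercept / slope_pct,
            "noise_sd": math.sqrt(_GRADIENT_FISH_MEAN) * per_fish_rate,
        })
    return bundles, pd.DataFrame(rows), truth
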