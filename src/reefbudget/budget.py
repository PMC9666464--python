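"""Site carbonate budget assembly and stratum aggregation.

Net carbonate production (NCP) is gross production (GCP) minus gross
erosion (GCE); a site with NCP < 0 is net erosional.  Budgets aggregate to
any ordered stratification (region, sub-region, reef type within
sub-region) as mean / standard error tables with the share of erosional
sites, and paired budget time series can be compared year by year for
model-validation style checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import erosion as _erosion
from . import production as _production
from .production import BudgetConfig, ProductionBreakdown
from .erosion import ErosionBreakdown
from .rugosity import DemGrid, site_rugosity
from .survey_io import (
    BenthicSurvey,
    CodeMap,
    CoralTrait,
    EroderConstants,
    FishSurvey,
    ParrotfishParams,
    SiteRecord,
    SurveyError,
    parrotfish_biomass,
    percent_cover,
)

__all__ = ["SiteBudget", "StratumSummary", "compute_site_budget", "summarize",
           "budgets_to_frame", "compare_trajectories"]


@dataclass
class SiteBudget:
    """One site's assembled carbonate budget (kg CaCO3 m^-2 yr^-1)."""

    site: SiteRecord
    rugosity: float
    gcp: float
    gce: float
    ncp: float
    production_breakdown: ProductionBreakdown
    erosion_breakdown: ErosionBreakdown
    coral_cover_pct: float
    parrotfish_biomass_kg_ha: float
    flags: set[str] = field(default_factory=set)

    @property
    def erosional(self) -> bool:
        return self.ncp < 0


@dataclass
class StratumSummary:
    labels: dict[str, str]
    n_sites: int
    mean_ncp: float
    se_ncp: float
    mean_gcp: float
    se_gcp: float
    mean_gce: float
    se_gce: float
    percent_erosional: float
    flags: set[str] = field(default_factory=set)


def compute_site_budget(
    benthic: BenthicSurvey,
    fish: FishSurvey,
    traits: Mapping[str, CoralTrait],
    params: ParrotfishParams,
    code_map: CodeMap,
    constants: EroderConstants | None = None,
    config: BudgetConfig | None = None,
    dem: DemGrid | None = None,
    dem_center: tuple[float, float] | None = None,
    rugosity: float | None = None,
) -> SiteBudget:
    """Assemble the budget for one site.

    Site rugosity comes either from ``rugosity`` directly or from clipping
    a 15 m ROI out of ``dem`` around ``dem_center``.  Deterministic for
    fixed inputs; any component failure is re-raised with the site id.
    """
    constants = constants or EroderConstants()
    config = config or BudgetConfig()
    flags: set[str] = set()
    try:
        if rugosity is None:
            if dem is None:
                raise SurveyError("need either a rugosity value or a DEM")
            center = dem_center if dem_center is not None else (
                (dem.x_range()[0] + dem.x_range()[1]) / 2,
                (dem.y_range()[0] + dem.y_range()[1]) / 2,
            )
            res = site_rugosity(dem, center)
            rugosity = res.rugosity
            flags |= res.flags
        if rugosity < 1.0 - 1e-9:
            raise SurveyError(f"rugosity {rugosity} below 1")

        cover = percent_cover(benthic)
        prod = _production.gross_production(cover, traits, code_map, rugosity, config)
        eros = _erosion.gross_erosion(cover, fish, benthic.urchin_count, params,
                                      code_map, constants, rugosity, config)
        gcp = prod.gross_production
        gce = eros.gross_erosion
        coral_pct = 100.0 * sum(f for c, f in cover.items() if code_map.is_coral(c))
        biomass = parrotfish_biomass(fish, params)
    except Exception as exc:
        raise type(exc)(f"site {benthic.site.site_id}: {exc}") from exc
    return SiteBudget(
        site=benthic.site,
        rugosity=rugosity,
        gcp=gcp,
        gce=gce,
        ncp=gcp - gce,
        production_breakdown=prod,
        erosion_breakdown=eros,
        coral_cover_pct=coral_pct,
        parrotfish_biomass_kg_ha=biomass,
        flags=flags,
    )


def budgets_to_frame(budgets: Sequence[SiteBudget]) -> pd.DataFrame:
    """Flatten budgets to a tidy DataFrame (one row per site)."""
    rows = []
    for b in budgets:
        rows.append({
            "site_id": b.site.site_id,
            "region": b.site.region,
            "subregion": b.site.subregion,
            "reef_type": b.site.reef_type,
            "year": b.site.year,
            "rugosity": b.rugosity,
            "gcp": b.gcp,
            "gce": b.gce,
            "ncp": b.ncp,
            "coral_cover_pct": b.coral_cover_pct,
            "parrotfish_biomass_kg_ha": b.parrotfish_biomass_kg_ha,
            "erosion_parrotfish": b.erosion_breakdown.parrotfish,
            "erosion_microborer": b.erosion_breakdown.microborer,
            "erosion_macroborer": b.erosion_breakdown.macroborer,
            "erosion_urchin": b.erosion_breakdown.urchin,
        })
    return pd.DataFrame(rows)


def summarize(budgets: Sequence[SiteBudget],
              by: Sequence[str] = ("region",)) -> list[StratumSummary]:
    """Stratum mean/SE table over an ordered list of grouping keys.

    ``by`` entries are SiteRecord fields (``region``, ``subregion``,
    ``reef_type``, ``year``).  SE uses the sample SD over sqrt(n); a
    single-site stratum reports SE 0 with an ``n_eq_1`` flag so tables
    serialize cleanly.
    """
    if not budgets:
        return []
    df = budgets_to_frame(budgets)
    out: list[StratumSummary] = []
    for key, grp in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        flags: set[str] = set()

        def se(x: pd.Series) -> float:
            if n == 1:
                flags.add("n_eq_1")
                return 0.0
            return float(x.std(ddof=1) / np.sqrt(n))

        out.append(StratumSummary(
            labels=dict(zip(by, (str(k) for k in key))),
            n_sites=n,
            mean_ncp=float(grp["ncp"].mean()), se_ncp=se(grp["ncp"]),
            mean_gcp=float(grp["gcp"].mean()), se_gcp=se(grp["gcp"]),
            mean_gce=float(grp["gce"].mean()), se_gce=se(grp["gce"]),
            percent_erosional=float((grp["ncp"] < 0).mean()),
            flags=flags,
        ))
    return out


def summaries_to_frame(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    """Serialize stratum summaries; erosion means print with a leading minus."""
    rows = []
    for s in summaries:
        row = dict(s.labels)
        row.update({
            "n_sites": s.n_sites,
            "mean_ncp": s.mean_ncp, "se_ncp": s.se_ncp,
            "mean_gcp": s.mean_gcp, "se_gcp": s.se_gcp,
            "mean_gce": -s.mean_gce, "se_gce": s.se_gce,
            "percent_erosional": s.percent_erosional,
            "flags": ";".join(sorted(s.flags)),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def compare_trajectories(series_a: Mapping[int, "StratumSummary | SiteBudget"],
                         series_b: Mapping[int, "StratumSummary | SiteBudget"]) -> dict:
    """Descriptive comparison of two budget time series on common years.

    Returns per-year deltas (a minus b) for NCP/GCP/GCE and the
    sign-agreement rate of year-over-year changes; no hypothesis test is
    attached — this mirrors a visual paired-trajectory check.
    """
    years = sorted(set(series_a) & set(series_b))
    if not years:
        raise SurveyError("no common years between the two series")

    def vals(obj):
        if isinstance(obj, SiteBudget):
            return obj.ncp, obj.gcp, obj.gce
        return obj.mean_ncp, obj.mean_gcp, obj.mean_gce

    deltas = {}
    for y in years:
        a, b = vals(series_a[y]), vals(series_b[y])
        deltas[y] = {"ncp": a[0] - b[0], "gcp": a[1] - b[1], "gce": a[2] - b[2]}

    agree = {}
    for i, metric in enumerate(("ncp", "gcp", "gce")):
        matches = []
        for y0, y1 in zip(years, years[1:]):
            da = vals(series_a[y1])[i] - vals(series_a[y0])[i]
            db = vals(series_b[y1])[i] - vals(series_b[y0])[i]
            matches.append(np.sign(da) == np.sign(db))
        agree[metric] = float(np.mean(matches)) if matches else 1.0

    return {"years": years, "deltas": deltas, "sign_agreement": agree}
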