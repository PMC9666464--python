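# Methods

## The carbonate budget model

A reef's framework persists when biological calcium carbonate production
outpaces its removal. The package quantifies this balance per survey site as

    NCP = GCP − GCE        (kg CaCO₃ m⁻² yr⁻¹)

where gross carbonate production (GCP) sums calcification by scleractinian
corals, crustose coralline algae (CCA) and other calcareous encrusters
(hydrocorals by default), and gross carbonate erosion (GCE) sums framework
removal by four bioeroder guilds: parrotfish, endolithic microborers,
excavating (clionid) sponges, and *Diadema* urchins. The accounting follows
the census-based ReefBudget tradition, with the important departure that
topographic complexity enters as a single site-level rugosity measured from
a DEM rather than as per-colony rugosity along the transect.

### Production

For each calcifying taxon *s* with planar cover fraction `c_s` (from a
100-point line point-intercept transect), linear extension rate `g_s`
(cm yr⁻¹), skeletal density `ρ_s` (g cm⁻³) and site rugosity `R`:

    P_s = c_s · g_s · ρ_s · 10 · m(morph_s) · R

The factor 10 converts g cm⁻² yr⁻¹ over a square meter to kg m⁻² yr⁻¹.
`m(·)` is a morphology conversion factor; all four morphologies default to
1.0 on the argument that the DEM-derived site rugosity already carries the
three-dimensionality that colony-scale geometry factors would otherwise
inject, and that encrusting/massive morphologies dominate the modern
assemblage this tool targets. The factors remain exposed in `BudgetConfig`
for users who want branching taxa amplified.

### Erosion

* **Parrotfish** — each censused fish removes
  `bite_rate · foraging_minutes_per_year · bite_volume · scar_proportion ·
  substrate_density` grams of framework annually; site totals divide by the
  census area (two 15 m diameter cylinders, 353.43 m²). The substrate
  density is fixed at 1.72 g cm⁻³. Foraging time defaults to 6 daylight
  hours × 365 days = 131 400 min yr⁻¹, configurable because published
  estimates vary with latitude and season.
* **Microborers** — 0.240 kg m⁻² yr⁻¹ × cover of dead coral substrate.
  "Dead substrate" is the union of codes flagged `dead_substrate` in the
  benthic code map; bare/dead substrate is flagged by default, turf is not
  (turf canopies overgrow both dead framework and sediment veneers, so
  including them would overcount; the flag is one line of YAML to flip).
* **Macroborers** — 6.05 kg m⁻² yr⁻¹ × clionid-sponge cover. Clionid
  sponges are a separate transect code from other sponges precisely so this
  term uses only the excavating fraction.
* **Urchins** — *Diadema* density × 0.003 kg urchin⁻¹ yr⁻¹, the rate of a
  mean-test-size (66 mm) individual; counts ride on the benthic transect
  with a default belt area of 15 m². Test-size-resolved erosion is out of
  scope by design since census protocols rarely record it.

Erosion terms are stored positive and subtracted at budget assembly;
reports print them with a leading minus. Which terms scale by rugosity is a
genuinely open design point: cover-driven (area-based) terms describe
processes on the true reef surface sampled by a planar transect, so they
multiply by `R` like production does, while the fish census counts
individuals over a planar cylinder and is therefore already areal. This is
the default (`rugosity_scaling: {production: true, area_erosion: true,
census_erosion: false}`); all three toggles are config.

### Rugosity

Rugosity is the ratio of 3D surface area to planimetric area over a
15 m × 15 m region of interest centered on the site coordinate of a
projected-CRS DEM (1 m LiDAR topobathymetry in the intended use).
Numerical choices, all fixed for reproducibility:

* ROI edges snap **outward** to cell boundaries (a center on a cell corner
  yields 16 cells per axis at 1 m, a center on a cell center yields 15).
* Elevations are point samples; each 2×2 block of samples forms a quad
  split along the NW–SE diagonal into two triangles whose exact 3D areas
  are summed. The planimetric reference is the same quad support
  (`n_quads · cell²`), so the ratio is exactly 1 for a flat grid and ≥ 1
  always. The diagonal choice perturbs the area by well under 0.5 % on
  smooth surfaces.
* Any quad touching a NoData sample is dropped from **both** areas, keeping
  the ratio unbiased; an ROI with > 50 % NoData carries a `high_nodata`
  flag. Inputs must already be projected in meters — no geodesy.

DEM I/O is plain-text ESRI ASCII grid (single band, NoData honored).

## Parameter tables

Every constant the equations consume lives in shipped, overridable text
tables: `coral_traits.csv` (per-species extension, density, morphology,
calcifier flag), `parrotfish_params.csv` (per species × 10 cm size bin:
bite rate, bite volume, scar proportion, length–weight `W = a·L^b`),
`benthic_codes.yml` (the closed code vocabulary with role flags) and
`eroder_constants.yml`. Extension/density values are representative
Caribbean literature magnitudes for a weedy-dominated assemblage; the
grazing table was sized so that a site holding ~100 kg ha⁻¹ of parrotfish
biomass erodes a few tenths of kg CaCO₃ m⁻² yr⁻¹, the magnitude census
studies report for Florida and the wider Caribbean. They are defensible
defaults, not measurements; any serious application should substitute
locally calibrated tables.

Fish lengths use the size-bin midpoint, unbiased under a uniform
within-bin length distribution and the convention stationary visual census
data support.

## Statistics

* **Driver regressions** — OLS of NCP on live coral cover (%) or
  parrotfish biomass (kg ha⁻¹), reporting slope, intercept, R², the slope F
  and p (displayed as "<0.0001" below that cutoff). The **coral-cover
  threshold** for positive reef growth is the fitted zero crossing
  `−intercept/slope`, defined only when the slope is positive and the
  crossing lies inside the observed cover range; its CI is a percentile
  bootstrap over sites (default 2000 resamples, seeded), since a point
  threshold alone is not honestly reusable.
* **Stratum GLMs** — NCP/GCP/GCE across sub-regions with reef type nested
  within sub-region. The response family is chosen by AIC over {normal,
  shifted lognormal, shifted gamma}; budget responses include negative
  values, so positive-support candidates are fit after a location shift of
  `min − 10⁻⁶·range`. Ties and samples under n = 10 fall back to normal
  (with a warning). Factor tests are sequential nested-deviance F tests,
  which reduce to classical ANOVA F under the normal family; the identity
  link and the absence of a year covariate are defaults of this package,
  not claims about any prior analysis. Under a two-group null simulation
  the test's type-I error at α = 0.05 sits inside [0.03, 0.07]
  (500 replicates, fixed seed — verified in the acceptance suite).

## Synthetic survey campaign

The generator emulates the stratified monitoring design end to end so the
whole pipeline runs and is tested without any external data: 723 sites
(DRTO 228; Lower/Middle/Upper Keys and Biscayne 103/46/140/33 summing to
the 322-site Florida Keys region; SEFL 173), reef types rotating within
strata (none in SEFL, where reef-type classification is absent), survey
years drawn from {2014, 2016, 2018}.

* **Benthic cover** — per-stratum category means follow the published
  regional cover table; SDs are recovered from the reported standard errors
  as `SE·√n`. Per-site cover vectors are clipped-normal draws renormalized
  onto the simplex. Clipping and renormalization shift marginal means, so
  the generator solves the clipped-normal location analytically per
  category (locations may be negative, which is how rare categories like
  seagrass reach sub-percent means) and polishes with a few damped Monte
  Carlo corrections; realized means land within ~0.05 cover points of
  target. The transect is then a 100-point multinomial draw. Coral cover
  splits over six species (PAST, SSID, OFAV, MCAV, PPOR, ACER) by a
  fixed-weight Dirichlet; 10 % of sponge cover is clionid.
* **Parrotfish** — per-site biomass targets are lognormal with regional
  mean/SD (DRTO 48.4 ± 40.2, FLK 118.7 ± 160.9, SEFL 57.1 ± 93.2 kg ha⁻¹),
  realized as Poisson counts over a fixed species × size-bin biomass
  composition, so realized regional means are unbiased for the targets.
* **DEMs** — 19 × 19 m smoothed Gaussian random fields at 1 m cells, with
  reef-type-specific amplitude giving mean rugosities from ~1.03 (SEFL
  low-relief hard bottom) to ~1.2 (offshore/bank), the range 1 m LiDAR
  products resolve.
* **Urchins** — Poisson with mean 0.05 per transect: functionally
  irrelevant, matching their observed regional scarcity.

What the generator does **not** emulate: spatial autocorrelation between
neighboring sites, zero-inflation/overdispersion structure of real cover
data beyond clipping, covariance between coral cover and parrotfish
biomass, within-region bathymetric realism, or observer error. Passing
tests on this fixture therefore demonstrate the *accounting and inference
machinery* — not that the shipped trait tables reproduce any particular
real-world survey's numbers.

Known-truth scenarios back the oracle tests: `all_zero` (pure sand, every
budget term 0), `only_microboring` (100 % bare substrate, NCP exactly
−0.240), and `linear_cover_gradient`, where a single massive coral against
bare substrate makes true NCP exactly linear in measured cover with
residual noise realized physically as Poisson parrotfish counts of known
per-fish erosion — so the regression stage's slope, intercept and zero
crossing have analytic targets.

## Problem sizes and numerical tolerances

Dual-implementation agreement of the site budget is checked on 200
randomized sites at 1e-9; budget additivity at 1e-12; rugosity against
closed forms at 1e-6 (planes) and 1 % (sinusoid vs quadrature, 5 cm cells);
parameter recovery over 100 seeds of 80-site gradient scenarios (2-SE
coverage and across-seed unbiasedness); GLM calibration over 500 null
replicates of 120 observations. The default end-to-end campaign is the full
723-site design, which runs in seconds.

## Known limitations

* Trait and grazing tables are documented placeholders; absolute budget
  levels track their values linearly.
* Site-level rugosity under- or over-corrects individual colonies; the
  morphology factors exist to compensate but default to neutral.
* The GLM stage models strata as fixed effects; no spatial or temporal
  random effects.
* The threshold estimator is a ratio of regression coefficients and is
  slightly biased at small n; the bootstrap CI is the honest summary.
* GeoTIFF DEMs are not read directly; convert to ESRI ASCII first.
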