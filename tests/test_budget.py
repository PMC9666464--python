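import math

import numpy as np
import pytest

import reefbudget as rb

from conftest import make_benthic
from oracle import load_tables, oracle_site_budget


def budget_for(site, counts, code_map, traits, params, fish_obs=(), urchins=0,
               rugosity=1.0):
    benthic = make_benthic(site, counts, urchins=urchins)
    fish = rb.FishSurvey(site=site, observations=list(fish_obs))
    return rb.compute_site_budget(benthic, fish, traits, params, code_map,
                                  rugosity=rugosity)


class TestComputeSiteBudget:
    def test_all_sand_no_fish_all_zero(self, site, code_map, traits, params):
        b = budget_for(site, {"sand": 100}, code_map, traits, params)
        assert b.gcp == 0.0 and b.gce == 0.0 and b.ncp == 0.0
        assert not b.erosional

    def test_pure_microboring_site(self, site, code_map, traits, params):
        b = budget_for(site, {"bare": 100}, code_map, traits, params)
        assert math.isclose(b.ncp, -0.240, rel_tol=1e-12)
        assert b.erosional

    def test_ncp_is_gcp_minus_gce(self, site, code_map, traits, params):
        b = budget_for(site, {"PAST": 20, "bare": 30, "clionid_sponge": 2},
                       code_map, traits, params,
                       fish_obs=[("SPA_VIR", (20.0, 30.0), 4)], urchins=3,
                       rugosity=1.3)
        assert b.ncp == b.gcp - b.gce
        assert abs(b.ncp - (b.production_breakdown.gross_production
                            - b.erosion_breakdown.gross_erosion)) < 1e-12

    def test_deterministic_for_fixed_inputs(self, site, code_map, traits, params):
        kw = dict(counts={"SSID": 10, "bare": 40}, code_map=code_map,
                  traits=traits, params=params,
                  fish_obs=[("SCA_ISE", (10.0, 20.0), 6)], rugosity=1.2)
        assert budget_for(site, **kw).ncp == budget_for(site, **kw).ncp

    def test_error_carries_site_id(self, site, code_map, traits, params):
        fish = rb.FishSurvey(site=site, observations=[("GONE", (0.0, 10.0), 1)])
        benthic = make_benthic(site, {"sand": 100})
        with pytest.raises(Exception, match="S1"):
            rb.compute_site_budget(benthic, fish, traits, params, code_map,
                                   rugosity=1.0)

    def test_rugosity_from_dem_clip(self, site, code_map, traits, params):
        dem = rb.DemGrid(elevations=np.full((19, 19), -20.0), cell_size_m=1.0)
        b = rb.compute_site_budget(make_benthic(site, {"bare": 100}),
                                   rb.FishSurvey(site=site), traits, params,
                                   code_map, dem=dem, dem_center=(9.5, 9.5))
        assert abs(b.rugosity - 1.0) <= 1e-9

    def test_scaling_covers_and_counts_scales_terms(self, site, code_map,
                                                    traits, params):
        b1 = budget_for(site, {"PAST": 10, "bare": 20}, code_map, traits,
                        params, fish_obs=[("SPA_VIR", (20.0, 30.0), 2)])
        b2 = budget_for(site, {"PAST": 20, "bare": 40}, code_map, traits,
                        params, fish_obs=[("SPA_VIR", (20.0, 30.0), 4)])
        assert math.isclose(b2.gcp, 2 * b1.gcp, rel_tol=1e-12)
        assert math.isclose(b2.erosion_breakdown.parrotfish,
                            2 * b1.erosion_breakdown.parrotfish, rel_tol=1e-12)
        assert math.isclose(b2.erosion_breakdown.microborer,
                            2 * b1.erosion_breakdown.microborer, rel_tol=1e-12)


class TestDualImplementationOracle:
    def test_randomized_sites_agree_with_straight_line_recomputation(
            self, site, code_map, traits, params):
        tables = load_tables()
        rng = np.random.default_rng(123)
        vocab = sorted(code_map.coral_species) + sorted(code_map.groups)
        fish_classes = sorted(tables["fish"])
        for _ in range(30):
            codes = tuple(rng.choice(vocab, size=100))
            n_classes = int(rng.integers(0, 4))
            picks = rng.permutation(len(fish_classes))[:n_classes]
            obs = [(fish_classes[i][0],
                    (fish_classes[i][1], fish_classes[i][1] + 10.0),
                    int(rng.integers(1, 9)))
                   for i in picks]
            urchins = int(rng.integers(0, 5))
            rug = float(rng.uniform(1.0, 2.5))
            benthic = rb.BenthicSurvey(site=site, point_codes=codes,
                                       urchin_count=urchins)
            fish = rb.FishSurvey(site=site, observations=obs)
            got = rb.compute_site_budget(benthic, fish, traits, params,
                                         code_map, rugosity=rug)
            want = oracle_site_budget(codes, [(sp, b[0], c) for sp, b, c in obs],
                                      urchins, fish.survey_area_m2, rug, tables)
            assert abs(got.gcp - want["gcp"]) < 1e-9
            assert abs(got.gce - want["gce"]) < 1e-9
            assert abs(got.ncp - want["ncp"]) < 1e-9


class TestSummarize:
    def make_budgets(self, code_map, traits, params, ncps):
        out = []
        for i, target in enumerate(ncps):
            site = rb.SiteRecord(f"S{i}", "DRTO", "DRTO", "bank", 24.6, -82.9, 2014)
            b = budget_for(site, {"sand": 100}, code_map, traits, params)
            b.ncp = b.gcp = target  # direct injection for aggregation arithmetic
            out.append(b)
        return out

    def test_single_site_se_zero_with_flag(self, code_map, traits, params):
        budgets = self.make_budgets(code_map, traits, params, [0.5])
        (s,) = rb.summarize(budgets, by=("region",))
        assert s.n_sites == 1 and s.se_ncp == 0.0 and "n_eq_1" in s.flags

    def test_two_sites_plus_minus_x(self, code_map, traits, params):
        x = 0.7
        budgets = self.make_budgets(code_map, traits, params, [x, -x])
        (s,) = rb.summarize(budgets, by=("region",))
        assert math.isclose(s.mean_ncp, 0.0, abs_tol=1e-15)
        # SE = SD/sqrt(2) with SD = x*sqrt(2) for the pair => SE = x
        assert math.isclose(s.se_ncp, x, rel_tol=1e-12)
        assert s.percent_erosional == 0.5

    def test_percent_erosional_scale_invariant(self, code_map, traits, params):
        budgets = self.make_budgets(code_map, traits, params, [1.0, -0.2, -0.4, 0.3])
        (s1,) = rb.summarize(budgets, by=("region",))
        for b in budgets:
            b.ncp *= 1000.0
        (s2,) = rb.summarize(budgets, by=("region",))
        assert s1.percent_erosional == s2.percent_erosional == 0.5

    def test_nested_stratification_spec(self, small_campaign):
        _, budgets = small_campaign
        rows = rb.summarize(budgets, by=("subregion", "reef_type"))
        labels = {(r.labels["subregion"], r.labels["reef_type"]) for r in rows}
        assert ("DRTO", "bank") in labels and ("LK", "mid_channel") in labels
        assert sum(r.n_sites for r in rows) == len(budgets)


class TestCompareTrajectories:
    def _series(self, code_map, traits, params, ncps):
        out = {}
        for year, v in ncps.items():
            b = budget_for(rb.SiteRecord("S0", "FLK", "UK", "mid_channel",
                                         24.9, -80.6, year),
                           {"sand": 100}, code_map, traits, params)
            b.ncp = b.gcp = v
            out[year] = b
        return out

    def test_identical_series(self, code_map, traits, params):
        a = self._series(code_map, traits, params, {2014: 0.1, 2016: 0.3, 2018: -0.2})
        res = rb.compare_trajectories(a, a)
        assert all(d["ncp"] == 0 for d in res["deltas"].values())
        assert res["sign_agreement"]["ncp"] == 1.0

    def test_constant_shift(self, code_map, traits, params):
        a = self._series(code_map, traits, params, {2014: 0.1, 2016: 0.3})
        b = self._series(code_map, traits, params, {2014: 0.6, 2016: 0.8})
        res = rb.compare_trajectories(a, b)
        assert all(math.isclose(d["ncp"], -0.5) for d in res["deltas"].values())
        assert res["sign_agreement"]["ncp"] == 1.0

    def test_anticorrelated_series_by_enumeration(self, code_map, traits, params):
        a = self._series(code_map, traits, params, {2014: 0.0, 2016: 1.0, 2018: 0.0})
        b = self._series(code_map, traits, params, {2014: 1.0, 2016: 0.0, 2018: 1.0})
        res = rb.compare_trajectories(a, b)
        assert res["sign_agreement"]["ncp"] == 0.0
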