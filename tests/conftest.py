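import numpy as np
import pytest

import reefbudget as rb


@pytest.fixture(scope="session")
def code_map():
    return rb.load_code_map()


@pytest.fixture(scope="session")
def traits():
    return rb.load_coral_traits()


@pytest.fixture(scope="session")
def params():
    return rb.load_parrotfish_params()


@pytest.fixture(scope="session")
def constants():
    return rb.load_eroder_constants()


@pytest.fixture
def site():
    return rb.SiteRecord(site_id="S1", region="DRTO", subregion="DRTO",
                         reef_type="bank", lat=24.6, lon=-82.9, year=2014)


def make_benthic(site, counts: dict[str, int], urchins: int = 0) -> rb.BenthicSurvey:
    """Transect with the given code multiset, padded to 100 with sand."""
    codes: list[str] = []
    for code, n in counts.items():
        codes.extend([code] * n)
    codes.extend(["sand"] * (100 - len(codes)))
    return rb.BenthicSurvey(site=site, point_codes=tuple(codes), urchin_count=urchins)


@pytest.fixture(scope="session")
def small_campaign(code_map, traits, params):
    """A compact synthetic campaign with budgets, shared across stats tests."""
    cfg = rb.FixtureConfig(site_counts={"DRTO": 45, "LK": 24, "MK": 12,
                                        "UK": 24, "BISC": 12, "SEFL": 30},
                           seed=7)
    bundles = rb.generate_fixture(cfg)
    budgets = [
        rb.compute_site_budget(b.benthic, b.fish, traits, params, code_map,
                               dem=b.dem, dem_center=b.dem_center)
        for b in bundles
    ]
    return bundles, budgets


@pytest.fixture
def rng():
    return np.random.default_rng(42)
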