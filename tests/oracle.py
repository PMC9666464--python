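"""Independent straight-line recomputation of a site carbonate budget.

Deliberately separate from the package internals: parameter tables are read
directly from the shipped CSV/YAML text with the stdlib csv/yaml readers and
the arithmetic is written out longhand, so agreement with
``compute_site_budget`` is a genuine dual-implementation check rather than
the same code called twice.  Assumes the default configuration: every
morphology factor 1, production and area-based erosion scaled by rugosity,
census (parrotfish) erosion not.
"""

from __future__ import annotations

import csv
from collections import Counter
from importlib import resources

import yaml


def _read_data(name: str) -> str:
    return resources.files("reefbudget.data").joinpath(name).read_text()


def load_tables() -> dict:
    traits = {}
    for row in csv.DictReader(_read_data("coral_traits.csv").splitlines()):
        traits[row["species_code"]] = {
            "extension": float(row["extension_cm_yr"]),
            "density": float(row["density_g_cm3"]),
            "calcifier": row["calcifier"].strip().lower() == "true",
        }
    fish = {}
    for row in csv.DictReader(_read_data("parrotfish_params.csv").splitlines()):
        fish[(row["species_code"], float(row["bin_lo_cm"]))] = {
            "rate": float(row["bite_rate_bites_min"]),
            "vol": float(row["bite_volume_cm3"]),
            "scar": float(row["scar_proportion"]),
        }
    groups = yaml.safe_load(_read_data("benthic_codes.yml"))["groups"]
    consts = yaml.safe_load(_read_data("eroder_constants.yml"))
    return {"traits": traits, "fish": fish, "groups": groups, "consts": consts}


def oracle_site_budget(point_codes, fish_obs, urchin_count, fish_area_m2,
                       rugosity, tables) -> dict:
    """Budget for one site from first principles.

    ``fish_obs`` is a list of (species_code, bin_lo, count).
    Returns gcp, gce, ncp and the four erosion guild terms (kg m^-2 yr^-1).
    """
    traits = tables["traits"]
    groups = tables["groups"]
    consts = tables["consts"]

    counts = Counter(point_codes)
    gcp = 0.0
    for code, n in counts.items():
        if code in traits and traits[code]["calcifier"]:
            cover = n / 100.0
            gcp += cover * traits[code]["extension"] * traits[code]["density"] * 10.0 * rugosity

    parrot = 0.0
    for sp, lo, count in fish_obs:
        p = tables["fish"][(sp, lo)]
        grams = (p["rate"] * consts["foraging_minutes_per_year"] * p["vol"]
                 * p["scar"] * consts["substrate_density_g_cm3"])
        parrot += count * grams / 1000.0
    parrot /= fish_area_m2

    dead = sum(n for c, n in counts.items()
               if c in groups and groups[c]["dead_substrate"]) / 100.0
    micro = dead * consts["microborer_rate_kg_m2_yr"] * rugosity

    clionid = sum(n for c, n in counts.items()
                  if c in groups and groups[c]["clionid"]) / 100.0
    macro = clionid * consts["clionid_rate_kg_m2_yr"] * rugosity

    urchin = (urchin_count / consts["urchin_survey_area_m2"]) \
        * consts["diadema_rate_kg_urchin_yr"] * rugosity

    gce = parrot + micro + macro + urchin
    return {"gcp": gcp, "gce": gce, "ncp": gcp - gce, "parrotfish": parrot,
            "microborer": micro, "macroborer": macro, "urchin": urchin}
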