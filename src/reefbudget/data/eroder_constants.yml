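# Fixed bioeroder rate constants (stored positive, applied as losses).
substrate_density_g_cm3: 1.72      # density of bitten reef framework
microborer_rate_kg_m2_yr: 0.240    # per unit cover of dead coral substrate
clionid_rate_kg_m2_yr: 6.05        # per unit cover of clionid sponge
diadema_rate_kg_urchin_yr: 0.003   # Diadema at mean test size 66 mm
foraging_minutes_per_year: 131400  # 6 daylight foraging hours x 365 days
urchin_survey_area_m2: 15.0        # belt area of the benthic transect
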