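species_code,morphology,extension_cm_yr,density_g_cm3,calcifier
PAST,massive,0.31,1.42,true
SSID,massive,0.38,1.54,true
OFAV,massive,0.75,1.45,true
MCAV,massive,0.42,1.72,true
PPOR,branching,1.50,1.28,true
ACER,branching,3.00,1.28,true
CCA,encrusting_plating,0.07,1.56,true
hydrocoral,encrusting_plating,0.45,1.34,true
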