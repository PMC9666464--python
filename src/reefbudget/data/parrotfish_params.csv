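species_code,bin_lo_cm,bin_hi_cm,bite_rate_bites_min,bite_volume_cm3,scar_proportion,lw_a,lw_b
SCA_ISE,0,10,20.0,0.001,0.01,0.0140,3.05
SCA_ISE,10,20,15.0,0.004,0.05,0.0140,3.05
SCA_ISE,20,30,10.0,0.012,0.08,0.0140,3.05
SCA_ISE,30,40,8.0,0.025,0.10,0.0140,3.05
SPA_AUR,0,10,12.0,0.002,0.02,0.0198,2.96
SPA_AUR,10,20,10.0,0.008,0.06,0.0198,2.96
SPA_AUR,20,30,8.0,0.020,0.10,0.0198,2.96
SPA_AUR,30,40,6.0,0.040,0.12,0.0198,2.96
SPA_VIR,0,10,6.0,0.002,0.05,0.0197,3.05
SPA_VIR,10,20,5.5,0.030,0.15,0.0197,3.05
SPA_VIR,20,30,5.0,0.120,0.30,0.0197,3.05
SPA_VIR,30,40,4.5,0.350,0.40,0.0197,3.05
SCA_VET,0,10,8.0,0.005,0.05,0.0105,3.12
SCA_VET,10,20,7.0,0.040,0.12,0.0105,3.12
SCA_VET,20,30,6.0,0.100,0.20,0.0105,3.12
SCA_VET,30,40,5.0,0.250,0.30,0.0105,3.12
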