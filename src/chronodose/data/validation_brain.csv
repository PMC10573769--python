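label,pct_dose_peak_reported,pct_dose_tmax_reported
passive_diffusion,30.70,117
carrier_amine,0.23,50
carrier_neutral_amino_acid,2.12,61
carrier_t3,0.18,193
nanoparticle,5.48,380
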