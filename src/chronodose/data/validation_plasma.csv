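label,substrate,dose_mg,auc_yp_measured,auc_yp_reported,cmax_yp_measured,cmax_yp_reported
passive_diffusion,melatonin,2.00,2.37e-4,2.31e-4,3.40e-6,4.67e-6
carrier_t3,triiodothyronine,0.05,1.12e-3,1.94e-3,3.46e-6,3.81e-6
carrier_amine,choline,550.00,0.40,0.30,1.04e-3,2.30e-3
carrier_neutral_amino_acid,L-dopa,100.00,8.48e-2,0.12,9.46e-4,1.13e-3
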