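# Published parameter sets for the five oral BBB transport systems.
# Rates 1/min, volumes mL, Vmax mg/min, km mg/mL (plasma concentration at
# half-maximal carrier transport), F bioavailability fraction.
passive_diffusion:
  model_family: passive_diffusion
  F: 0.14
  ka: 0.11
  ke: 0.11
  kbb: 4.53e-2
  kebb: 2.82e-2
  Vp: 1.80e+5
  Vb: 3.30e+5
carrier_amine:
  model_family: carrier_mediated
  F: 0.80
  ka: 2.90e-2
  ke: 0.10
  kebb: 3.38e-2
  Vp: 3.00e+4
  Vb: 0.90e+4
  Vmax: 10.00
  km: 0.44
carrier_neutral_amino_acid:
  model_family: carrier_mediated
  F: 0.30
  ka: 1.40e-2
  ke: 1.30e-2
  kebb: 2.82e-2
  Vp: 1.00e+4
  Vb: 0.30e+4
  Vmax: 30.00
  km: 0.12
carrier_t3:
  model_family: carrier_mediated
  F: 0.75
  ka: 4.00e-3
  ke: 0.02
  kebb: 1.30e-2
  Vp: 1.50e+4
  Vb: 3.00e+4
  Vmax: 0.10
  km: 1.00e-3
nanoparticle:
  model_family: nanoparticle
  F: 0.14
  ka: 0.11
  ke: 0.11
  kbb: 6.10e-3
  kebb: 8.30e-4
  Vp: 1.80e+5
  Vb: 3.30e+5
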