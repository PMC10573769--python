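# Published receding-horizon tuning per transport system: cumulative dose
# ceiling umax (mg over one prediction horizon) and input weight wu.
passive_diffusion:           {umax: 2.00,  wu: 1.00}
carrier_amine:               {umax: 16.50, wu: 1.00e-3}
carrier_neutral_amino_acid:  {umax: 3.00,  wu: 0.10}
carrier_t3:                  {umax: 4.30,  wu: 0.10}
nanoparticle:                {umax: 0.06,  wu: 1.00}
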