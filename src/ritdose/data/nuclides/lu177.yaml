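# 177Lu -> 177Hf : beta-minus with low-abundance gamma
name: Lu177
half_life_h: 161.0
daughter_Z: 72
charge_sign: -1
p_gamma: 0.1722
main_gamma_energy_MeV: 0.208
main_gamma_abundance: 0.061
p_e: 1.0
mean_beta_energy_MeV: 0.133
mean_beta_range_mm: 0.26
beta_branches:
  - {endpoint_MeV: 0.497, fraction: 0.786}
  - {endpoint_MeV: 0.385, fraction: 0.091}
  - {endpoint_MeV: 0.176, fraction: 0.123}
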