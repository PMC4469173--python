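# 188Re -> 188Os : high-energy beta-minus with low-abundance gamma
name: Re188
half_life_h: 16.9
daughter_Z: 76
charge_sign: -1
p_gamma: 0.1981
main_gamma_energy_MeV: 0.155
main_gamma_abundance: 0.15
p_e: 1.0
mean_beta_energy_MeV: 0.764
mean_beta_range_mm: 3.1
beta_branches:
  - {endpoint_MeV: 2.120, fraction: 0.710}
  - {endpoint_MeV: 1.965, fraction: 0.266}
  - {endpoint_MeV: 1.487, fraction: 0.024}
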