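# 131I -> 131Xe : beta-minus with abundant gamma
name: I131
half_life_h: 192.0
daughter_Z: 54
charge_sign: -1
p_gamma: 1.0980
main_gamma_energy_MeV: 0.365
main_gamma_abundance: 0.853
p_e: 1.0
mean_beta_energy_MeV: 0.132
mean_beta_range_mm: 0.26
beta_branches:
  - {endpoint_MeV: 0.606, fraction: 0.899}
  - {endpoint_MeV: 0.334, fraction: 0.073}
  - {endpoint_MeV: 0.248, fraction: 0.028}
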