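# 90Y -> 90Zr : pure beta-minus emitter
name: Y90
half_life_h: 64.1
daughter_Z: 40
charge_sign: -1
p_gamma: 0.0
main_gamma_energy_MeV: null
main_gamma_abundance: null
p_e: 1.0
mean_beta_energy_MeV: 0.935
mean_beta_range_mm: 4.0
beta_branches:
  - {endpoint_MeV: 2.280, fraction: 1.0}
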