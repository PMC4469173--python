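# 124I -> 124Te : positron emitter with abundant gamma.
# The two branches carry mean positron energies 0.686 and 0.974 MeV; their
# endpoints are calibrated per branch against those target means.
name: I124
half_life_h: 100.0
daughter_Z: 52
charge_sign: +1
p_gamma: 1.6380
main_gamma_energy_MeV: 0.603
main_gamma_abundance: 0.629
p_e: 0.2327
mean_beta_energy_MeV: null
mean_beta_range_mm: 4.1
beta_branches:
  - {endpoint_MeV: 1.535, fraction: 0.1216, target_mean_MeV: 0.686}
  - {endpoint_MeV: 2.138, fraction: 0.1111, target_mean_MeV: 0.974}
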