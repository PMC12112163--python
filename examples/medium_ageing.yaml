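# Full desk-scale study: 300 heterogeneous neurons, 3 s, Young vs Aged.
# Run with:  emcosim compare-ageing -c examples/medium_ageing.yaml -o ageing_report
population: medium
T: 3000.0
mode: coupled
seed: 7
t_coupling: 100.0
record_stride: 0.5
calibration:
  enabled: true
  band: [1.0, 10.0]
  budget: 6
ageing_profile: aged
profiles:
  aged:
    etc_efficiency_factor: 0.85
    glc_art_factor: 0.80
    glc_intracellular_factor: 0.80
    bhb_factor: 0.70
    lac_n_initial_factor: 1.20
    nad_tot_factor: 0.70
    nadh_shuttle_factor: 0.75
    glutamate_drive_factor: 0.80
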