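# Default synthetic-population specification (version 1).
#
# The archetype mix mirrors the across-speed category counts observed in
# zebra finch pretectal recordings (36 directional-to-omnidirectional, 32
# mostly directional, 24 mostly omnidirectional and 22 variable cells out
# of 114); the variable slice is realized as 12 bidirectional plus 10
# unmodulated cells.  The wide/dense protocol split mirrors the 48 cells
# recorded with the wide six-speed program and 66 with the dense ten-speed
# program.  Parameter ranges put the population speed-tuning peak at
# 32-64 deg/s and the directional-to-omnidirectional transition between 64
# and 128 deg/s.
version: 1
n_cells: 114
n_sweeps: 10
wide_fraction: 0.4211  # 48 of 114 cells on the wide protocol
archetype_mix:
  dir_to_omni: 0.3158      # 36 / 114
  directional: 0.2807      # 32 / 114
  omnidirectional: 0.2105  # 24 / 114
  bidirectional: 0.1053    # 12 / 114
  unmodulated: 0.0877      # 10 / 114
cell_params:
  spont_range: [4.0, 8.0]        # spikes/s
  gain_over_spont: 10.0          # peak_gain = 10 x spont (high SNR)
  kappa0_range: [3.5, 4.5]
  kappa_decay_dir_to_omni: 0.25  # per octave above speed_center
  speed_center_choices: [16, 32, 32, 32, 64]  # deg/s, modal 32
  speed_sigma_range: [2.5, 3.5]  # octaves
  transient_gain_slope_range: [0.25, 0.35]  # per octave
  it_gain_range: [1.3, 1.7]
  latency_base_range: [170.0, 190.0]  # ms at 1 deg/s
  latency_slope_range: [12.0, 16.0]   # ms per octave
  tn_fraction: 0.65  # fraction of directional-family cells preferring 0 deg
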