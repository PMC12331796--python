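# Color flanker experiment: red/green squares, 6 x 5,940 trials.
design:
  n_participants: 6
  n_sessions: 5
  blocks_per_session: 9
  trials_per_block: 132
  gap_levels_ms: [0, 100, 200, 300, 400, 500, 600, 700, 800, 900, 950]
  fixation_levels_ms: [350, 400, 500]
  soa_levels_ms: [0]
  deadline_ms: 1000
  practice_blocks: 1
observer:
  p_floor: 0.5
  p_asym: 0.97
  rise_mid_ms: 250
  rise_scale_ms: 40
  congruency_delay_ms: 50
  dip_depth: 0.0
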