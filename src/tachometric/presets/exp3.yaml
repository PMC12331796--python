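# Processing-asymmetry experiment: flankers may lead the target by 120 ms.
# The observer's dip (active only on incongruent trials with SOA > 0) is
# calibrated so the generative restricted minimum is 0.16, centered 400 ms.
design:
  n_participants: 6
  n_sessions: 5
  blocks_per_session: 4
  trials_per_block: 264
  gap_levels_ms: [0, 100, 200, 300, 400, 500, 600, 700, 800, 900, 950]
  fixation_levels_ms: [350, 400, 500]
  soa_levels_ms: [0, 120]
  deadline_ms: 1000
  practice_blocks: 1
observer:
  p_floor: 0.5
  p_asym: 0.97
  rise_mid_ms: 250
  rise_scale_ms: 40
  congruency_delay_ms: 50
  dip_center_ms: 400
  dip_width_ms: 80
  dip_soa_gated: true
  dip_target_min: 0.16
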