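session_id: FI001-c2
child_id: FI001
country: Fiji
campaign: 2
season: dry
age_group: 6m-<2y
sex: F
mobility: walking only
clips:
- clip_id: FI001-c2-k01
  duration_s: 240.0
  coder_id: truth
- clip_id: FI001-c2-k02
  duration_s: 240.0
  coder_id: truth
- clip_id: FI001-c2-k03
  duration_s: 60.0
  coder_id: truth
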