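session_id: FI002-c1
child_id: FI002
country: Fiji
campaign: 1
season: wet
age_group: 2-<5y
sex: F
mobility: walking only
clips:
- clip_id: FI002-c1-k01
  duration_s: 240.0
  coder_id: truth
- clip_id: FI002-c1-k02
  duration_s: 240.0
  coder_id: truth
- clip_id: FI002-c1-k03
  duration_s: 60.0
  coder_id: truth
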