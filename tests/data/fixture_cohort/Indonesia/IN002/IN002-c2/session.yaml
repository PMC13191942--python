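session_id: IN002-c2
child_id: IN002
country: Indonesia
campaign: 2
season: wet
age_group: 2-<5y
sex: F
mobility: walking only
clips:
- clip_id: IN002-c2-k01
  duration_s: 240.0
  coder_id: truth
- clip_id: IN002-c2-k02
  duration_s: 240.0
  coder_id: truth
- clip_id: IN002-c2-k03
  duration_s: 60.0
  coder_id: truth
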