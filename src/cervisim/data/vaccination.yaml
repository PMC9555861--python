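coverage:
  1965: 0.0
  1975: 0.0
  1985: 0.35
efficacy_16_18: 0.95
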