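# Anti-PCSK9 antibody and PCSK9 both present from t = 0; PCSK9 at 1e14.
scenario:
  initial:
    p_E: 1.0e+14
    A_E: 3.0e+14
  horizon_h: 300.0
  output_step_h: 0.5
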