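# Small-molecule anti-PCSK9 agent: antibody protocol with 10x association
# rate and 1/10 dissociation rate.
scenario:
  initial:
    p_E: 1.0e+14
    A_E: 3.0e+14
  horizon_h: 300.0
  output_step_h: 0.5
parameters:
  eps_p: 1.0e-13
  eps_minus_p: 1.0e-4
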