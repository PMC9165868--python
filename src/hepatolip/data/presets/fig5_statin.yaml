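# Single statin dose at 10 h on the baseline background.  Dose magnitude is
# an assumed default (not printed); override with --param or 'events'.
scenario:
  initial:
    p_E: 1.0e+12
  events:
    - time_h: 10.0
      species: statin_E
      mode: bolus
      amount: 5.0e+15
  horizon_h: 300.0
  output_step_h: 0.5
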