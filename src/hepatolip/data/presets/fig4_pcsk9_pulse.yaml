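# Timed external PCSK9 source: 1e12 molec./mL delivered over 10 min at 100 h.
scenario:
  events:
    - time_h: 100.0
      species: PCSK9_E
      mode: influx
      amount: 1.6666666666666666e+9   # molec./(mL s); 1e12 molec./mL over 600 s
      duration_h: 0.16666666666666666
  horizon_h: 300.0
  output_step_h: 0.5
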