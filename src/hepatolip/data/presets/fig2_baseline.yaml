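# Baseline kinetics: fresh medium, constant VLDL source, extracellular PCSK9
# preset to 1e12 molec./mL.
scenario:
  initial:
    p_E: 1.0e+12
  horizon_h: 200.0
  output_step_h: 0.5
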