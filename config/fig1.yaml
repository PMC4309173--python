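C_lum_glc: 50.0
Q_cap: 1.0
Vmax_glut2_ap: 0.5
scenario:
  kind: factorial
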