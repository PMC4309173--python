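C_lum_glc: 30.0
Q_cap: 10.0
Vmax_glut2_ap: 2.0
scenario:
  kind: inhibitor_timecourse
  mode: A
schedule:
- sglt1_scale: 0.0
  time: 0.5
- glut2_ap_scale: 0.0
  sglt1_scale: 0.0
  time: 1.0
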