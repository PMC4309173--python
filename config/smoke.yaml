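C_lum_glc: 30.0
Q_cap: 10.0
Vmax_glut2_ap: 2.0
scenario:
  atol: 1.0e-08
  kind: inhibitor_timecourse
  mode: A
  report_dt: 0.02
  rtol: 1.0e-06
  t_end: 0.2
schedule:
- sglt1_scale: 0.0
  time: 0.1
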