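C_art_Na: 150.0
C_art_glc: 5.0
C_lum_Na: 150.0
C_lum_glc: 50.0
Km_Na_bl: 25.0
Km_glut2: 17.0
Km_pump: 20.0
Km_sglt1_Na: 30.0
Km_sglt1_glc: 17.9
Lp_ap: 0.00015
Lp_bl: 0.00015
Lp_cap: 0.03
Lp_pc: 3.0e-05
P_Na_pc: 0.03
P_cap_Na: 2.0
P_cap_glc: 1.36
P_glc_pc: 0.015
Q_cap: 10.0
V_cap: 0.1
V_cyt_ref: 0.55
Vmax_Na_bl: 2.5
Vmax_glut2_ap: 2.0
Vmax_glut2_bl: 13.3
Vmax_pump: 8.3
Vmax_sglt1: 1.63
cap_flow: 1.36
compliance_V0: 0.3
compliance_k: 5.0
flux_scale: 60.0
lymph_coeff: 0.001
n_Na_per_glc: 2.0
n_imp_cyt: 105.0
n_w_per_glc: 210.0
osmotic_factor: 19.3
pc_area_factor: 730.0
phloretin_blocks_water: false
pressure_floor: -3.0
sigma_Na: 0.8
sigma_glc: 0.9
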