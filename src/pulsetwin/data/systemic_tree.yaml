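fluid:
  density_kg_m3: 1060.0
  kinematic_viscosity_m2_s: 3.3e-06
reference_pressure_mmHg: 80.0
external_pressure_mmHg: 0.0
heart:
  heart_rate_bpm: 60.0
  ventricle:
    E_min_mmHg_per_mL: 0.09999999999999999
    E_max_mmHg_per_mL: 2.8
    V0_mL: 15.000000000000002
    t_rise: 0.3
    t_fall: 0.45
    onset: 0.0
  atrium:
    E_min_mmHg_per_mL: 0.14999999999999997
    E_max_mmHg_per_mL: 0.35
    V0_mL: 3.0
    t_rise: 0.09
    t_fall: 0.17
    onset: 0.85
  R_mitral_mmHg_s_per_mL: 0.04
  R_aortic_mmHg_s_per_mL: 0.024999999999999998
  R_venous_mmHg_s_per_mL: 0.045
  P_venous_mmHg: 10.0
outlets:
  celiac:
    Zc_mmHg_s_per_mL: 0.7529567674568769
    R_mmHg_s_per_mL: 2.0157885368256165
    C_mL_per_mmHg: 0.650113969391078
    Pout_mmHg: 10.0
  left_internal_iliac:
    Zc_mmHg_s_per_mL: 2.9525665834998835
    R_mmHg_s_per_mL: 6.353494022560721
    C_mL_per_mmHg: 0.19342233800065126
    Pout_mmHg: 10.0
  left_femoral:
    Zc_mmHg_s_per_mL: 2.7553960339677688
    R_mmHg_s_per_mL: 5.174028387764342
    C_mL_per_mmHg: 0.2270026050146533
    Pout_mmHg: 10.0
  right_internal_iliac:
    Zc_mmHg_s_per_mL: 2.9525665834998835
    R_mmHg_s_per_mL: 6.353494022560721
    C_mL_per_mmHg: 0.19342233800065126
    Pout_mmHg: 10.0
  right_femoral:
    Zc_mmHg_s_per_mL: 2.7553960339677688
    R_mmHg_s_per_mL: 5.174028387764342
    C_mL_per_mmHg: 0.2270026050146533
    Pout_mmHg: 10.0
  left_cerebral:
    Zc_mmHg_s_per_mL: 12.372659968951892
    R_mmHg_s_per_mL: 24.851582455290526
    C_mL_per_mmHg: 0.048355584500162814
    Pout_mmHg: 10.0
  left_external_carotid:
    Zc_mmHg_s_per_mL: 6.643274812874738
    R_mmHg_s_per_mL: 14.295361550761621
    C_mL_per_mmHg: 0.08596548355584502
    Pout_mmHg: 10.0
  right_cerebral:
    Zc_mmHg_s_per_mL: 12.372659968951892
    R_mmHg_s_per_mL: 24.851582455290526
    C_mL_per_mmHg: 0.048355584500162814
    Pout_mmHg: 10.0
  right_external_carotid:
    Zc_mmHg_s_per_mL: 6.643274812874738
    R_mmHg_s_per_mL: 14.295361550761621
    C_mL_per_mmHg: 0.08596548355584502
    Pout_mmHg: 10.0
  left_radial:
    Zc_mmHg_s_per_mL: 13.49744723885661
    R_mmHg_s_per_mL: 23.726795185385807
    C_mL_per_mmHg: 0.048355584500162814
    Pout_mmHg: 10.0
  left_ulnar:
    Zc_mmHg_s_per_mL: 9.916491848955879
    R_mmHg_s_per_mL: 17.431931156609984
    C_mL_per_mmHg: 0.06581732334744382
    Pout_mmHg: 10.0
  right_radial:
    Zc_mmHg_s_per_mL: 13.49744723885661
    R_mmHg_s_per_mL: 23.726795185385807
    C_mL_per_mmHg: 0.048355584500162814
    Pout_mmHg: 10.0
  right_ulnar:
    Zc_mmHg_s_per_mL: 9.916491848955879
    R_mmHg_s_per_mL: 17.431931156609984
    C_mL_per_mmHg: 0.06581732334744382
    Pout_mmHg: 10.0
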