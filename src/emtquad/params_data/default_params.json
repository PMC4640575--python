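{
 "J1_200": 7.0,
 "J1_34": 0.3,
 "J2_200": 1.75,
 "J2_34": 1.5,
 "J2_zeb": 0.13,
 "J_O": 0.35,
 "J_OT": 2.6,
 "J_T200": 0.15,
 "J_es": 2.0,
 "J_ez": 2.0,
 "J_ss": 10.0,
 "J_st": 4.0,
 "J_vo": 1.0,
 "J_vs": 1.5,
 "J_vz": 0.8,
 "J_zs": 2.0,
 "K_1": 1.0,
 "K_SR": 1.0,
 "gamma_200": [
  1.0,
  1.4,
  1.9,
  2.5,
  3.2,
  4.0,
  5.0
 ],
 "gamma_34": [
  1.0,
  4.0,
  10.0
 ],
 "k0_200": 0.01,
 "k0_34": 0.001,
 "k0_E": 0.005,
 "k0_V": 0.005,
 "k0_sm": 0.02,
 "k0_zm": 0.0017,
 "k_200": 0.4,
 "k_34": 0.5,
 "k_E": 1.0,
 "k_S": 150.0,
 "k_T": 0.8,
 "k_V": 1.0,
 "k_Z": 400.0,
 "k_sm": 0.05,
 "k_zm": 0.017,
 "kd_200": 1.0,
 "kd_34": 1.0,
 "kd_E": 0.5,
 "kd_O": 0.5,
 "kd_S": 0.5,
 "kd_T": 1.0,
 "kd_V": 0.5,
 "kd_Z": 1.0,
 "kd_sm": 1.0,
 "kd_zm": 1.0,
 "l_200": [
  1.0,
  0.5,
  0.25,
  0.12,
  0.06,
  0.03,
  0.015
 ],
 "l_34": [
  1.0,
  0.1,
  0.005
 ],
 "leak_O": 0.15,
 "mu0_200": 0.55,
 "mu0_34": 0.2,
 "n1_200": 2,
 "n1_34": 2,
 "n2_200": 6,
 "n2_34": 2,
 "n_O": 5,
 "n_OT": 6,
 "n_T200": 2,
 "n_es": 2,
 "n_ez": 2,
 "n_ss": 1,
 "n_st": 2,
 "n_vo": 2,
 "n_vs": 2,
 "n_vz": 2,
 "n_zeb": 6,
 "n_zs": 4,
 "ovol2_basal": 1.0,
 "tgfb_exo": 0.0
}
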