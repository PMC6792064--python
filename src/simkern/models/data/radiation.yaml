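rates:
  k_fix: 0.4
  K_fix: 5.0
  k_spont: 0.01
  b_atm: 0.1
  g_atm: 0.1
  k_aact: 1.0
  K_aact: 2.0
  k_adeph: 0.5
  K_adeph: 0.3
  g_atmp: 0.05
  k_chk: 0.3
  K_chk: 0.5
  g_chk: 0.2
  b_p53: 0.3
  k_mdm: 1.2
  K_mdm: 0.3
  K_arf: 0.3
  k_pact: 1.0
  K_pact: 0.5
  g_p53: 0.05
  k_pdeph: 0.5
  K_pdeph: 0.3
  k_tet: 0.6
  K_tet: 0.5
  g_p53p: 0.1
  k_mdm2t: 0.6
  g_ptet: 0.1
  b_mdm: 0.15
  v_mdm: 0.4
  K_vmdm: 0.5
  k_sdeg: 0.4
  K_sdeg: 0.3
  g_mdm: 0.15
  v_wip: 0.3
  K_vwip: 0.5
  g_wip: 0.15
  b_arf: 0.05
  v_arf: 0.2
  K_varf: 0.5
  g_arf: 0.1
  b_siah: 0.05
  v_siah: 0.2
  K_vsiah: 0.5
  g_siah: 0.1
  v_repr: 0.25
  K_vrepr: 0.6
  g_repr: 0.1
  v_p21: 0.5
  K_vp21: 0.4
  g_p21: 0.15
  v_gad: 0.3
  K_vgad: 0.5
  g_gad: 0.15
  v_sfn: 0.3
  K_vsfn: 0.5
  g_sfn: 0.15
  b_cdc: 0.2
  k_cdcin: 0.8
  K_cdcin: 0.3
  g_cdc: 0.15
  v_ce: 0.4
  K_vce: 0.3
  K_cep21: 0.3
  g_ce: 0.1
  v_cb: 0.5
  K_cbcdc: 0.5
  K_cbsfn: 0.4
  K_cbp21: 0.4
  g_cb: 0.1
  b_rb: 0.2
  k_rbp: 0.8
  K_rbp: 0.4
  g_rb: 0.1
  v_e2f: 0.4
  K_e2frb: 0.3
  g_e2f: 0.1
  v_puma: 0.4
  K_vpuma: 0.5
  g_puma: 0.1
  v_bax: 0.4
  K_vbax: 0.5
  k_bcl: 1.0
  K_bcl: 0.4
  g_bax: 0.1
  b_bcl2: 0.15
  k_pb: 0.8
  K_pb: 0.4
  g_bcl2: 0.1
  k_cyt: 0.4
  K_cyt: 0.5
  g_cyt: 0.1
  b_apaf: 0.15
  k_apop: 0.8
  K_apop: 0.4
  g_apaf: 0.1
  g_apop: 0.1
  k_c9: 0.4
  K_c9: 0.3
  g_c9: 0.1
  k_c3: 0.5
  K_c3: 0.3
  g_c3: 0.1
  k_parp: 0.4
  K_parp: 0.4
  g_parp: 0.02
  v_repair: 0.5
  K_vrep: 0.5
  K_repku: 0.5
  v_rep2: 0.2
  K_rep2: 0.5
  g_repair: 0.1
  b_ku: 0.1
  g_ku: 0.1
  k_cyc: 0.4
  K_cycb: 0.5
  K_cyce: 0.3
  K_cycrep: 0.4
  g_cyc: 0.1
  k_mit: 0.5
  K_mitb: 0.5
  K_mitd: 3.0
  g_mit: 0.02
  k_sen: 0.3
  K_senp: 0.4
  k_sen2: 0.3
  K_senr: 0.5
  g_sen: 0.1
initial_state:
  DSB: 20.0
  ATM: 2.0
  p53: 1.0
  MDM2: 0.5
  BCL2: 1.0
  APAF1: 1.0
  KU: 1.0
  RB: 1.5
  CDC25: 1.0
thresholds:
  apoptosis: 12.0
  mitotic: 6.0
  cycling: 0.5
  residual_dsb: 2.0
varied_params:
- k_fix
- k_aact
- k_adeph
- b_p53
- k_mdm
- k_pact
- k_tet
- v_mdm
- v_wip
- v_arf
- v_siah
- v_repr
- v_p21
- v_gad
- v_sfn
- k_cdcin
- v_ce
- v_cb
- k_rbp
- v_e2f
- v_puma
- v_bax
- k_bcl
- k_pb
- k_cyt
- k_apop
- k_c9
- k_c3
- k_parp
- v_repair
- k_cyc
- k_mit
- k_sen
uncertain_params:
- k_fix
- k_aact
- k_adeph
- b_p53
- k_mdm
- k_pact
- k_tet
- v_mdm
- v_wip
- v_arf
- v_siah
- v_repr
- v_p21
- v_gad
- v_sfn
- k_cdcin
- v_ce
- v_cb
- k_rbp
- v_e2f
- v_puma
- v_bax
- k_bcl
- k_pb
- k_cyt
- k_apop
- k_c9
- k_c3
- k_parp
- v_repair
- k_cyc
- k_mit
- k_sen
- g_atm
- g_atmp
- g_chk
- g_p53
- g_p53p
- g_ptet
- g_mdm
- g_wip
- g_arf
- g_siah
- g_repr
- g_p21
- g_gad
- g_sfn
- g_cdc
- g_ce
- g_cb
- g_rb
- g_e2f
- g_puma
- g_bax
- g_bcl2
- g_cyt
- g_apaf
- g_apop
- g_c9
- g_c3
- g_parp
- g_repair
- g_ku
- g_cyc
- g_mit
- g_sen
- K_fix
- K_aact
- K_adeph
- K_mdm
- K_arf
- K_pact
- K_tet
- K_vmdm
- K_vp21
- K_vbax
- K_vpuma
- K_cep21
- K_cbcdc
- K_e2frb
- K_bcl
- K_apop
- K_c9
- K_c3
- K_parp
- K_vrep
- K_cycb
vary_sigma: 0.6
mutation_prob: 0.3
simkern_sd: 0.2
classification_variables:
- DSB
- PARPc
- MITDAM
- CYCLING
horizon: 48.0
dt: 0.05
out_every: 0.5
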