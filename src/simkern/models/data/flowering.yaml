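rates:
  b_FT: 0.05
  v_FT: 0.08
  K_FT: 1.0
  g_FT: 0.1
  b_FD: 0.1
  v_FD: 0.1
  K_FD: 0.5
  g_FD: 0.1
  b_S: 0.02
  v_S1: 0.2
  K_S1a: 0.5
  K_S1b: 0.5
  v_S2: 0.1
  K_S2: 0.5
  g_S: 0.1
  b_A: 0.02
  v_A1: 0.15
  K_A1: 0.5
  K_A2: 0.3
  g_A: 0.1
  b_L: 0.01
  v_L1: 0.1
  K_L1: 0.5
  v_L2: 0.1
  K_L2: 0.5
  v_L3: 0.3
  K_L3: 0.5
  g_L: 0.12
  b_P: 0.005
  v_P1: 0.4
  K_P1: 0.6
  K_P3: 10.0
  v_P2: 0.08
  K_P2a: 0.5
  K_P2b: 0.5
  g_P: 0.12
threshold: 1.0
oe_factor: 8.0
vary_sigma: 0.3
perturbed_params:
- v_FT
- K_FT
- g_FT
- b_FD
- v_FD
- K_FD
- g_FD
- b_S
- v_S1
- K_S1a
- K_S1b
- v_S2
- K_S2
- g_S
- b_A
- v_A1
- K_A1
- K_A2
- g_A
- b_L
- v_L1
- K_L1
- v_L2
- K_L2
- v_L3
- K_L3
- g_L
- v_P1
- K_P1
- K_P3
- v_P2
- K_P2a
- K_P2b
- g_P
genotypes:
  WT: {}
  ft-ko:
    FT: ko
  fd-ko:
    FD: ko
  soc1-ko:
    SOC1: ko
  agl24-ko:
    AGL24: ko
  lfy-ko:
    LFY: ko
  ap1-ko:
    AP1: ko
  ft-oe:
    FT: oe
  fd-oe:
    FD: oe
  soc1-oe:
    SOC1: oe
  agl24-oe:
    AGL24: oe
  lfy-oe:
    LFY: oe
  ap1-oe:
    AP1: oe
  ft-soc1-ko:
    FT: ko
    SOC1: ko
  soc1-agl24-ko:
    SOC1: ko
    AGL24: ko
  ft-agl24-ko:
    FT: ko
    AGL24: ko
  ft-lfy-ko:
    FT: ko
    LFY: ko
  agl24-lfy-ko:
    AGL24: ko
    LFY: ko
  soc1-lfy-ko:
    SOC1: ko
    LFY: ko
horizon: 100.0
dt: 0.1
out_every: 1.0
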