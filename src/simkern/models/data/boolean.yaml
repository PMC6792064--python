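nodes:
- DNAdamage
- ECM
- GF
- TGFbeta
- NICD
- AKT1
- AKT2
- ERK
- GSK3
- NFkB
- CTNNB1
- DKK1
- p53
- p63
- p73
- miR34
- miR200
- miR203
- SNAI1
- SNAI2
- TWIST1
- ZEB1
- ZEB2
- CDH1
- CDH2
- EMT
- CellCycleArrest
- Apoptosis
- Invasion
- Migration
- Metastasis
- Proliferation
rules:
  DNAdamage: DNAdamage
  ECM: ECM
  GF: GF
  TGFbeta: ECM | NICD
  NICD: ECM & ~miR200 & ~miR34 & ~p53
  AKT1: GF & (NICD | TGFbeta | CTNNB1) & ~miR34 & ~p53
  AKT2: (TWIST1 | GF) & (TGFbeta | NICD) & ~miR203
  ERK: GF | NICD | TGFbeta
  GSK3: ~AKT1 & ~AKT2 & ~NICD
  NFkB: AKT1 | AKT2 | TGFbeta
  CTNNB1: ~GSK3 & ~CDH1 & ~p53
  DKK1: CTNNB1 | NICD
  p53: (DNAdamage | NICD) & ~AKT1 & ~AKT2
  p63: DNAdamage & ~NICD & ~AKT1 & ~AKT2
  p73: DNAdamage & ~ZEB1 & ~AKT1
  miR34: (p53 | p63 | p73) & ~SNAI1 & ~ZEB1 & ~ZEB2
  miR200: (p63 | p73) & ~SNAI2 & ~ZEB1 & ~ZEB2
  miR203: p53 & ~SNAI1 & ~ZEB2
  SNAI1: (NICD | CTNNB1 | NFkB) & ~miR34 & ~p53
  SNAI2: (TWIST1 | CTNNB1 | NFkB) & ~miR200 & ~miR203 & ~p53
  TWIST1: CTNNB1 | NICD
  ZEB1: (SNAI1 | TWIST1 | NICD) & ~miR200
  ZEB2: (SNAI1 | SNAI2 | NICD) & ~miR200 & ~miR203
  CDH1: ~SNAI1 & ~SNAI2 & ~ZEB1 & ~ZEB2 & ~TWIST1
  CDH2: TWIST1 | ZEB1
  EMT: CDH2 & ~CDH1
  CellCycleArrest: (miR34 | miR200 | miR203 | p53) & ~EMT
  Apoptosis: (p53 | p63 | p73) & ~ZEB2 & ~AKT1 & ~AKT2
  Invasion: CTNNB1 | (EMT & TGFbeta)
  Migration: EMT & Invasion & ~Apoptosis & ~miR200
  Metastasis: Migration
  Proliferation: (ERK | CTNNB1) & ~CellCycleArrest & ~Apoptosis & ~p53
mutation_states:
  p53: 0
  AKT1: 1
  AKT2: 1
  NICD: 1
  TGFbeta: 1
init_prob:
  ECM: 0.3
  DNAdamage: 0.6
mutation_prob: 0.12
markers:
  apoptotic: Apoptosis
  metastasizing: Metastasis
modules:
  Damage:
  - DNAdamage
  Microenv:
  - ECM
  - GF
  NotchTGF:
  - TGFbeta
  - NICD
  Kinase:
  - AKT1
  - AKT2
  - ERK
  - GSK3
  - NFkB
  Wnt:
  - CTNNB1
  - DKK1
  TumorSupp:
  - p53
  - p63
  - p73
  miRNA:
  - miR34
  - miR200
  - miR203
  EMTreg:
  - SNAI1
  - SNAI2
  - TWIST1
  - ZEB1
  - ZEB2
  Adhesion:
  - CDH1
  - CDH2
  - EMT
  Death:
  - Apoptosis
  - CellCycleArrest
  Motility:
  - Invasion
  - Migration
  - Metastasis
  - Proliferation
reduced_rules:
  Damage: Damage
  Microenv: Microenv
  NotchTGF: Microenv
  Kinase: Microenv | NotchTGF
  Wnt: NotchTGF & ~TumorSupp
  TumorSupp: Damage & ~Kinase & ~EMTreg
  miRNA: TumorSupp & ~EMTreg
  EMTreg: (NotchTGF | Wnt | Kinase) & ~miRNA & ~TumorSupp
  Adhesion: EMTreg
  Death: TumorSupp & ~EMTreg & ~Kinase
  Motility: EMTreg & Adhesion & ~Death & ~TumorSupp
reduced_markers:
  apoptotic: Death
  metastasizing: Motility
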