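species:
- name: IL1
  compartment: membrane
  initial_nM: 0.0
- name: IL1R
  compartment: membrane
  initial_nM: 100.0
- name: IL1R_complex
  compartment: membrane
  initial_nM: 0.0
- name: IRAK
  compartment: cytosol
  initial_nM: 100.0
- name: pIRAK
  compartment: cytosol
  initial_nM: 0.0
- name: TRAF6
  compartment: cytosol
  initial_nM: 100.0
- name: pIRAK_TRAF6
  compartment: cytosol
  initial_nM: 0.0
- name: TAB2
  compartment: cytosol
  initial_nM: 100.0
- name: IRAK_TRAF6_TAB2
  compartment: membrane
  initial_nM: 0.0
- name: TAB2_TRAF6
  compartment: cytosol
  initial_nM: 0.0
- name: TAK1
  compartment: cytosol
  initial_nM: 100.0
- name: pTAK1
  compartment: cytosol
  initial_nM: 0.0
- name: TAB1
  compartment: cytosol
  initial_nM: 10.0
- name: TAB1_p38
  compartment: cytosol
  initial_nM: 0.0
- name: pp38_cyt
  compartment: cytosol
  initial_nM: 0.0
- name: MKK
  compartment: cytosol
  initial_nM: 100.0
- name: pMKK
  compartment: cytosol
  initial_nM: 0.0
- name: p38
  compartment: cytosol
  initial_nM: 100.0
- name: pp38_nuc
  compartment: nucleus
  initial_nM: 0.0
- name: MKP1
  compartment: nucleus
  initial_nM: 100.0
reactions:
- name: il1_receptor_binding
  reactants:
    IL1: 1
    IL1R: 1
  products:
    IL1R_complex: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.01
- name: irak_phosphorylation
  reactants:
    IRAK: 1
  products:
    pIRAK: 1
  modifiers:
  - IL1R_complex
  rate_law:
    kind: michaelis_menten
    kcat: 30.0
    Km: 10.0
- name: pirak_traf6_binding
  reactants:
    pIRAK: 1
    TRAF6: 1
  products:
    pIRAK_TRAF6: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.01
- name: membrane_complex_assembly
  reactants:
    pIRAK_TRAF6: 1
    TAB2: 1
  products:
    IRAK_TRAF6_TAB2: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.01
- name: irak_degradation_release
  reactants:
    IRAK_TRAF6_TAB2: 1
  products:
    TAB2_TRAF6: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.05
- name: tak1_activation_by_tab2_traf6
  reactants:
    TAK1: 1
  products:
    pTAK1: 1
  modifiers:
  - TAB2_TRAF6
  rate_law:
    kind: michaelis_menten
    kcat: 0.2
    Km: 100.0
- name: tab2_traf6_degradation
  reactants:
    TAB2_TRAF6: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.016
- name: tak1_activation_by_tab1
  reactants:
    TAK1: 1
  products:
    pTAK1: 1
  modifiers:
  - TAB1
  rate_law:
    kind: mass_action
    k: 9.3e-06
- name: ptak1_dephosphorylation
  reactants:
    pTAK1: 1
  products:
    TAK1: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.02
- name: ptak1_degradation
  reactants:
    pTAK1: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.0002
- name: tab1_production_induced
  reactants: {}
  products:
    TAB1: 1
  modifiers:
  - pTAK1
  rate_law:
    kind: saturating_induction
    Vmax: 0.045
    K: 10.0
- name: mkk_phosphorylation
  reactants:
    MKK: 1
  products:
    pMKK: 1
  modifiers:
  - pTAK1
  rate_law:
    kind: michaelis_menten
    kcat: 0.025
    Km: 200.0
- name: pmkk_dephosphorylation
  reactants:
    pMKK: 1
  products:
    MKK: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.016
- name: p38_phosphorylation_nuclear
  reactants:
    p38: 1
  products:
    pp38_nuc: 1
  modifiers:
  - pMKK
  rate_law:
    kind: michaelis_menten
    kcat: 0.07
    Km: 100.0
- name: pp38_dephosphorylation_by_mkp1
  reactants:
    pp38_nuc: 1
  products:
    p38: 1
  modifiers:
  - MKP1
  rate_law:
    kind: michaelis_menten
    kcat: 0.012
    Km: 20.0
- name: mkp1_production_basal
  reactants: {}
  products:
    MKP1: 1
  modifiers: []
  rate_law:
    kind: zero_order_production
    alpha: 0.02083164
- name: mkp1_production_induced
  reactants: {}
  products:
    MKP1: 1
  modifiers:
  - pp38_nuc
  rate_law:
    kind: saturating_induction
    Vmax: 0.02
    K: 0.2
- name: mkp1_decay
  reactants:
    MKP1: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.00028881132523331054
- name: tab1_p38_binding
  reactants:
    TAB1: 1
    p38: 1
  products:
    TAB1_p38: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.0001
- name: tab1_p38_dissociation
  reactants:
    TAB1_p38: 1
  products:
    TAB1: 1
    p38: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.05
- name: p38_autophosphorylation
  reactants:
    TAB1_p38: 1
  products:
    pp38_cyt: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.00066
- name: pp38_cyt_dephosphorylation
  reactants:
    pp38_cyt: 1
  products:
    TAB1_p38: 1
  modifiers: []
  rate_law:
    kind: mass_action
    k: 0.0002
- name: tab2_production_basal
  reactants: {}
  products:
    TAB2: 1
  modifiers: []
  rate_law:
    kind: zero_order_production
    alpha: 0.01
- name: tab2_decay
  reactants:
    TAB2: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.0001
- name: traf6_production_basal
  reactants: {}
  products:
    TRAF6: 1
  modifiers: []
  rate_law:
    kind: zero_order_production
    alpha: 0.01
- name: traf6_decay
  reactants:
    TRAF6: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.0001
- name: tak1_production_basal
  reactants: {}
  products:
    TAK1: 1
  modifiers: []
  rate_law:
    kind: zero_order_production
    alpha: 0.0500959
- name: tak1_decay
  reactants:
    TAK1: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.0005
- name: tab1_production_basal
  reactants: {}
  products:
    TAB1: 1
  modifiers: []
  rate_law:
    kind: zero_order_production
    alpha: 0.01051926
- name: tab1_decay
  reactants:
    TAB1: 1
  products: {}
  modifiers: []
  rate_law:
    kind: first_order_decay
    beta: 0.00125
conserved_groups:
- - MKK
  - pMKK
- - TAB1_p38
  - p38
  - pp38_cyt
  - pp38_nuc
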