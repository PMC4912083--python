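format: il1p38-parameters-v1
# Committed calibrated parameter set for the IL-1/p38 network (nM, s).
# Produced by the package's calibration path against the behaviour checklist:
# nuclear pp38 pulse peaking near 120 s at 100 nM IL-1, return to the basal
# band near 3724 s, dose robustness 100 vs 1 nM, step-like cytosolic pp38,
# all deletion/level phenotypes, wild-type levels TAB1 = 10 nM,
# TAB2 = 100 nM, MKP1 = 100 nM.  See docs/methods.md.
parameters:
  kon_il1_receptor:
    value: 0.01
    unit: 1/(nM*s)
    provenance: calibrated
  kcat_irak:
    value: 30.0
    unit: 1/s
    provenance: calibrated
  km_irak:
    value: 10.0
    unit: nM
    provenance: calibrated
  kon_pirak_traf6:
    value: 0.01
    unit: 1/(nM*s)
    provenance: calibrated
  kon_tab2_membrane:
    value: 0.01
    unit: 1/(nM*s)
    provenance: calibrated
  kdeg_irak:
    value: 0.05
    unit: 1/s
    provenance: calibrated
  kcat_tak1:
    value: 0.2
    unit: 1/s
    provenance: calibrated
  km_tak1:
    value: 100.0
    unit: nM
    provenance: calibrated
  k_tab1_tak1:
    value: 9.3e-06
    unit: 1/(nM*s)
    provenance: calibrated
  kdephos_ptak1:
    value: 0.02
    unit: 1/s
    provenance: calibrated
  beta_ptak1:
    value: 0.0002
    unit: 1/s
    provenance: calibrated
  beta_tab2_traf6:
    value: 0.016
    unit: 1/s
    provenance: calibrated
  alpha_tab2:
    value: 0.01
    unit: nM/s
    provenance: calibrated
  beta_tab2:
    value: 0.0001
    unit: 1/s
    provenance: calibrated
  alpha_traf6:
    value: 0.01
    unit: nM/s
    provenance: calibrated
  beta_traf6:
    value: 0.0001
    unit: 1/s
    provenance: calibrated
  alpha_tak1:
    value: 0.0500959
    unit: nM/s
    provenance: calibrated
  beta_tak1:
    value: 0.0005
    unit: 1/s
    provenance: calibrated
  alpha_tab1:
    value: 0.01051926
    unit: nM/s
    provenance: calibrated
  beta_tab1:
    value: 0.00125
    unit: 1/s
    provenance: calibrated
  vmax_tab1_induction:
    value: 0.045
    unit: nM/s
    provenance: calibrated
  k_tab1_induction:
    value: 10.0
    unit: nM
    provenance: calibrated
  kcat_mkk:
    value: 0.025
    unit: 1/s
    provenance: calibrated
  km_mkk:
    value: 200.0
    unit: nM
    provenance: calibrated
  kdephos_pmkk:
    value: 0.016
    unit: 1/s
    provenance: calibrated
  kcat_p38:
    value: 0.07
    unit: 1/s
    provenance: calibrated
  km_p38:
    value: 100.0
    unit: nM
    provenance: calibrated
  kcat_mkp1:
    value: 0.012
    unit: 1/s
    provenance: calibrated
  km_mkp1:
    value: 20.0
    unit: nM
    provenance: calibrated
  alpha_mkp1:
    value: 0.02083164
    unit: nM/s
    provenance: calibrated
  beta_mkp1:
    half_life: 40.0
    unit: min
    provenance: calibrated
  vmax_mkp1_induction:
    value: 0.02
    unit: nM/s
    provenance: calibrated
  k_mkp1_induction:
    value: 0.2
    unit: nM
    provenance: calibrated
  kon_tab1_p38:
    value: 0.0001
    unit: 1/(nM*s)
    provenance: calibrated
  koff_tab1_p38:
    value: 0.05
    unit: 1/s
    provenance: calibrated
  kauto_p38:
    value: 0.00066
    unit: 1/s
    provenance: calibrated
  kdephos_pp38cyt:
    value: 0.0002
    unit: 1/s
    provenance: calibrated
  level_il1r:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_irak:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_traf6:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_tab2:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_tak1:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_tab1:
    value: 10.0
    unit: nM
    provenance: calibrated
  level_mkk:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_p38:
    value: 100.0
    unit: nM
    provenance: calibrated
  level_mkp1:
    value: 100.0
    unit: nM
    provenance: calibrated
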