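# Interaction-model configuration: the final composite midazolam / 1'-OH-midazolam population model:
# typical values, covariate exponents, variability and residual error.
# Volumes in L, clearances in L/h, rate constants in 1/h, variances on the
# log scale, proportional-error magnitudes dimensionless.
population:
  Vc: 19.5        # midazolam central volume [L]
  Vp1: 41.0       # midazolam peripheral-1 volume [L]
  Vp2: 23.8       # midazolam peripheral-2 volume [L]
  Qp1: 8.00       # midazolam inter-compartment clearance 1 [L/h]
  Qp2: 46.1       # midazolam inter-compartment clearance 2 [L/h]
  ka: 2.31        # first-order absorption rate constant [1/h]
  F: 0.276        # combined oral bioavailability
  kmet: 5.31      # pre-systemic metabolism rate constant [1/h]
  Qmet: 24.1      # midazolam clearance via metabolism [L/h]
  Vmet: 175.6     # metabolite central volume [L]
  Vmp: 684.9      # metabolite peripheral-1 volume [L]
  Vmp2: 67.1      # metabolite peripheral-2 volume [L]
  Qmp: 59.6       # metabolite inter-compartment clearance 1 [L/h]
  theta_weight: 0.986   # power of weight (ref 70 kg) on Qmp
  Qmp2: 127.4     # metabolite inter-compartment clearance 2 [L/h]
  CLmet: 196.8    # metabolite elimination clearance [L/h]
  fm_systemic: 1.0
  err_early_mdz: 0.503
  err_late_mdz: 0.149
  err_early_ohmdz: 0.556
  err_late_ohmdz: 0.215
  err_split_h: 0.5
  ref_weight_kg: 70.0
  ref_age_y: 26.5
random_effects:
  omega2:
    Vc: 0.378
    Vp1: 0.410
    Qp1: 0.502
    F: 0.234
    kmet: 0.369
    Qmet: 0.0934
    Vmet: 0.398
    Qmp: 0.485
    CLmet: 0.133
  corr_Vc_Vmet: 0.731
  iov2:
    F: 0.162
    Qmet: 0.152
    CLmet: 0.293
# CYP3A-modulation (treatment) effects of the interaction model.
# Additive deltas on kmet [1/h], Qmet / CLmet [L/h] and Vc [L]; fractional
# change on F (F -> F * (1 + f_F)).  Inhibition arms use their own
# proportional-error pair with the early/late split moved to 1.5 h.
treatment_effects:
  constitutive: {}
  induction:
    d_kmet: 12.4
    f_F: -0.200
    d_Qmet: 38.0
  reversible_inhibition:
    f_F: 0.379
    d_Qmet: -16.3
    d_CLmet: -64.1
    err_early_inh: 0.483
    err_late_inh: 0.267
    err_split_override_h: 1.5
  irreversible_inhibition:
    d_Vc: 51.8
    d_kmet: -5.24
    f_F: 1.34
    d_Qmet: -12.7
    d_CLmet: 1117.0
    err_early_inh: 0.483
    err_late_inh: 0.267
    err_split_override_h: 1.5
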