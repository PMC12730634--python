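# Default parameter registry for the CAPE tumour-microenvironment digital twin.
#
# Units: time in hours, cell populations in absolute cell counts, signalling
# species (cytokines C, stiffness S, proteases MMP, HIF activity H, VEGF V,
# vessel density A) in arbitrary units, oxygen in mmHg (scaled), CAPE dose in
# micromolar.  Entries marked "calibrated, this artifact" were fitted by the
# shipped calibration routines (see docs/methods.md) and are reproduced
# deterministically by `capetwin calibrate` / the reproduce subcommand.

tumour_immune:
  r: 0.05            # tumour intrinsic growth rate, 1/h
  K: 1.0e+06         # tumour carrying capacity, cells
  alpha_kill: 1.0e-07  # effector killing coefficient, 1/(cells*h)
  sE: 0.0            # dose-independent effector source, cells/h
  pE: 100.0          # antigen-driven effector stimulation rate, cells/h
  KE: 1.0e+05        # half-saturation for T-cell activation, cells
  dE: 0.05           # effector natural decay, 1/h
  alphaTreg: 0.0     # Treg suppression of effectors, 1/(cells*h); 0 uncoupled
  phi: 1.0           # CAPE enhancement of effector killing (dimensionless)
  eta: 1.0           # CAPE enhancement of effector stimulation (dimensionless)

immunoreg:
  rM1: 0.02          # baseline M1 growth rate, 1/h
  rM2: 0.02          # baseline M2 growth rate, 1/h
  Kmac: 1.0e+06      # shared macrophage niche capacity, cells
  aTregM1: 1.0e-03   # Treg suppression of M1, 1/(cells*h)
  bTregM2: 1.0e-03   # Treg promotion of M2, 1/(cells*h)
  gLacM2: 2.0e-03    # lactate-driven M2 expansion, 1/h (per unit L)
  sR: 0.01           # baseline Treg source, cells/h
  aM2R: 1.0e-07      # M2->Treg induction, 1/h (closure for the implicit
                     # cytokine/lactate Treg inputs; this artifact)
  dM1: 0.01          # M1 decay, 1/h
  dM2: 0.01          # M2 decay, 1/h
  dR: 0.005          # Treg decay, 1/h
  gM1: 0.005242      # CAPE boost of M1 expansion, 1/h (calibrated, this artifact)
  gM2: 0.158162      # CAPE attenuation of the immunosuppressive M2
                     # polarisation drive, dimensionless in [0,1]
                     # (calibrated, this artifact)
  gR: 0.957574       # CAPE attenuation of M2->Treg induction, dimensionless
                     # in [0,1] (calibrated, this artifact)
  # Text-form coefficients for the literal source/linear variant of the
  # R/M1/M2 equations.  No published values exist; they must be supplied
  # explicitly to run that variant.
  sM1: null
  sM2: null
  aM1E: null
  bL1: null
  bL2: null
  gC2: null
  aE2: null
  alphaR: null
  betaR: null

stroma:
  sF: 5.0            # baseline CAF source, cells/h
  aF: 1.0e-04        # tumour-driven CAF induction, 1/h (per tumour cell, scaled)
  gF: 1.0e-03        # cytokine-driven CAF induction, 1/h (per cytokine unit)
  dF: 0.01           # CAF turnover, 1/h
  kF_cape: 0.026153  # CAPE suppression of CAFs, 1/h, applied via f(D)
                     # (calibrated, this artifact; initial guess 1e-3)
  rT: 0.02           # baseline tumour proliferation in this block, 1/h
  KT: 1.0e+06        # tumour carrying capacity in this block, cells
  betaF: 1.0         # strength of the CAF boost on tumour growth (dimensionless)
  KF: 1.0e+04        # half-saturation for the CAF boost, cells
  aC: 1.0e-04        # tumour-driven cytokine production, a.u./h
  dC: 0.01           # cytokine clearance, 1/h

ecm:
  rhoS: 1.0e-03      # CAF-driven stiffening, a.u./h per CAF
  lamS: 1.0e-03      # M2-driven stiffening, a.u./h per M2 cell
  dS: 5.0e-03        # baseline softening, 1/h
  dS_mmp: 1.0e-04    # MMP-mediated degradation, 1/(a.u.*h)
  aMMP_T: 1.0e-04    # tumour-driven MMP production, a.u./h per cell
  aMMP_F: 1.0e-04    # CAF-driven MMP production, a.u./h per cell
  muMMP: 1.0e-02     # MMP decay, 1/h
  kMMPprod: 0.5      # CAPE weakening of CAF-driven MMP production (dimensionless)
  kMMPdeg: 0.5       # CAPE strengthening of MMP degradation (dimensionless)

hypoxia_angio:
  aH: 0.05           # basal HIF-1a induction, 1/h
  KO2: 20.0          # oxygen half-saturation for HIF suppression, mmHg
  KTH: 1.0e+05       # tumour half-saturation for HIF activation, cells
  dH: 0.01           # HIF degradation, 1/h
  O2base: 10.0       # baseline tissue oxygen, mmHg
  kO2: 0.60          # CAPE relative increase in effective oxygenation
  kAlpha: 0.40       # CAPE reduction of HIF induction
  kDelta: 0.50       # CAPE increase of HIF degradation
  krT: 0.35          # CAPE reduction of tumour proliferation
  kkill: 0.015       # CAPE direct tumour-kill coefficient, 1/h
  aV: 0.10           # HIF-driven VEGF production, 1/h
  dV: 0.02           # VEGF clearance, 1/h
  aA: 0.05           # VEGF-driven vessel growth, 1/h
  KVA: 50.0          # VEGF half-saturation for vessel growth, a.u.
  Amax: 100.0        # abnormal vessel capacity, a.u.
  dA: 0.01           # vessel pruning, 1/h

cape:
  IC50: 50.0         # half-maximal CAPE concentration, uM
  nH: 2.0            # Hill coefficient (dimensionless)
  delta_doses: [0.0, 10.0, 25.0, 50.0, 100.0]    # uM
  delta_values: [0.0, 0.02, 0.05, 0.08, 0.10]    # 1/h, dose-response mapping

initial_state:
  T: 1.0e+04
  E: 1.0e+02
  R: 1.0e+02
  M1: 1.0e+03
  M2: 1.0e+03
  F: 1.0e+02
  C: 0.0
  S: 0.0
  MMP: 0.0
  H: 0.0
  V: 0.0
  A: 0.0

simulation:
  t_end: 200.0       # hours
  dt_out: 1.0        # output grid spacing, hours
  method: LSODA
  rtol: 1.0e-06
  atol: 1.0e-09
  lactate_const: 0.5 # constant lactate proxy used by modular immunoreg runs
  dose_list: [0.0, 10.0, 25.0, 50.0, 100.0]
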