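# Methods

`capetwin` is an ODE "digital twin" of an in vitro ovarian-cancer (PA-1
teratocarcinoma) tumour microenvironment (TME) under exposure to CAPE
(caffeic acid phenethyl ester, a propolis-derived polyphenol).  It is an
experimentally anchored surrogate, not a patient-specific model: six
phenomenological model blocks reproduce the qualitative and headline
quantitative behaviour of the system at doses 0–100 μM over 0–200 h.

## Model blocks

All populations are in absolute cell counts, signalling species in
arbitrary units (a.u.), time in hours.  The CAPE dose D (μM) is constant
per run (no pharmacokinetics).  Dose enters through exactly one of two
mechanisms per block:

* the Hill fraction f(D) = D^nH / (D^nH + IC50^nH), IC50 = 50 μM, nH = 2,
  scaled by a per-channel gain; or
* in the tumour–immune block only, the tabulated suppression coefficient
  δ(D) ∈ {0, 0.02, 0.05, 0.08, 0.1} h⁻¹ at D ∈ {0, 10, 25, 50, 100} μM
  (piecewise-linear between mapped doses, clamped extrapolation beyond
  100 μM only on explicit request), together with the Hill-scaled
  effector gains φ and η.  No block double-counts the dose.

**Tumour–immune** (T, E):

    dT/dt = r T (1 − T/K) − α_kill E T (1 + φ f(D)) − δ(D) T
    dE/dt = sE + pE T/(T + KE) (1 + η f(D)) − dE E − α_Treg R E

The printed effector source "s = 100 cells/h" is implemented as the
antigen-driven stimulation rate pE (the activation term is described as
driven by tumour antigen load); the dose-independent source sE defaults
to 0.  φ = η = 1 by default.  δ(D)·T is an additive per-capita loss
(δ carries units h⁻¹).  α_Treg = 0 when the block runs uncoupled.

**Immunoregulation** (R, M1, M2), operational "table" variant:

    dM1/dt = rM1 M1 (1 − (M1+M2)/Kmac) − aTregM1 R M1 − dM1 M1 + gM1 f(D) M1
    dM2/dt = rM2 M2 (1 − (M1+M2)/Kmac)
             + (bTregM2 R + gLacM2 L) M2 (1 − gM2 f(D)) − dM2 M2
    dR/dt  = sR + aM2R M2 (1 − gR f(D)) − dR R

Both macrophage phenotypes share one niche capacity Kmac.  Lactate L is
the tumour-burden proxy T/KT in coupled runs and a constant (default
0.5, i.e. mid burden) in modular runs; it has no dynamics of its own.
The M2→Treg induction rate aM2R closes the "implicit" cytokine/lactate
Treg inputs; its default 1×10⁻⁷ h⁻¹ was chosen once so that (i) the Treg
pool stays bounded at dose 0 over 200 h — larger values make the
M2→Treg→M2 promotion loop outrun any logistic containment — and (ii)
Treg levels still decline monotonically with dose.  A literal
source/linear "text" variant of these equations is retained; it has no
published coefficients and must be parameterised explicitly.

The M2 attenuation gain gM2 acts on the *combined* immunosuppressive
polarisation drive (Treg promotion + lactate expansion).  This is a
deliberate design choice: with the printed rate constants the lactate
term alone contributes at most ~6% of M2 growth over 72 h, so no
admissible gain acting on lactate only could produce the ~50% M2
reduction the calibration targets.  Attenuating the whole suppressive
drive is consistent with the biology being modelled (CAPE damps
TGF-β/IL-10-mediated suppression) and makes the documented calibration
well-posed.

**CAF/stroma** (F, C, T):

    dF/dt = sF + aF T + gF C − dF F − kF_cape f(D) F
    dC/dt = aC T − dC C
    dT/dt = rT (1 + βF F/(KF + F)) (1 − krT f(D)) T (1 − T/KT)

CAFs are sourced by tumour cells and cytokines and suppressed by CAPE;
CAFs boost tumour proliferation through a saturating feedback (βF = 1,
KF = 10⁴ cells).  The tumour growth rate here (rT = 0.02 h⁻¹) is kept
distinct from the tumour–immune block's r = 0.05 h⁻¹, as tabulated; the
two blocks are separate projections of the same system and are not
reconciled.

**ECM/MMP** (S, MMP):

    dS/dt   = ρS F + λS M2 − δS S − δS' MMP S
    dMMP/dt = αMMP,T T + αMMP,F (1 − kMMPprod f(D)) F
              − μMMP (1 + kMMPdeg f(D)) MMP

Both CAPE channels are MMP-suppressive as tabulated (weakened
production, strengthened degradation).  The narrative claim that CAPE
*increases* relative MMP activity is inconsistent with those tabulated
channel definitions; the implementation follows the tables and the
discrepancy is documented here rather than engineered around.

**Hypoxia–HIF and VEGF–angiogenesis** (H, V, A, T):

    dH/dt = aH (1 − kα f) · [1/(1 + O2eff/KO2)] · [T/(KTH + T)]
            − dH (1 + kδ f) H,    O2eff = O2base (1 + kO2 f)
    dV/dt = aV H − dV V
    dA/dt = aA V/(KVA + V) (1 − A/Amax) − dA A
    dT/dt = rT (1 − krT f) T (1 − T/KT) − kkill f T

The vessel growth term is exactly as printed (no A factor on the
VEGF-driven term), so A relaxes to capacity with a saturating VEGF
gate; A ≤ Amax is invariant when A(0) ≤ Amax.  The direct CAPE kill
(kkill f T) lives only in this block's tumour copy, never alongside the
δ(D) mapping.

An extended structural tumour/effector form (saturating M1/M2
kill/support, hypoxic stress, APC/IL-2 priming, vessel- and
CXCL12-supported trafficking, Treg/stiffness/exhaustion losses) is
implemented as a right-hand side with *no* defaults: every coefficient
must be user-supplied, because none is published.

## Coupling modes

The shipped figures-style experiments are **modular**: each block set is
integrated by itself, which is also how the reference results were
produced.  The ECM block consumes F(t) and T(t) interpolated from a
stroma run and M2(t) from an immunoregulation run; the hypoxia block
evolves its own tumour compartment.  A **coupled** mode shares one joint
12-component state: lactate becomes T/KT, the tumour equation uses the
tumour–immune backbone with the CAF boost multiplying its proliferation
term and the hypoxia block's direct kill added, and the Treg–effector
coupling α_Treg is meant to be switched to 1×10⁻⁶ (cells·h)⁻¹.  Coupled
mode is provided for exploration; no headline number depends on it.

## Numerics

Adaptive integration via `scipy.integrate.solve_ivp` (LSODA, rtol 10⁻⁶,
atol 10⁻⁹), output on a uniform 1 h grid over 200 h.  All right-hand
sides are quasi-positive, so the exact flow preserves non-negativity;
the solver evaluates derivatives at states floored at zero, and output
values that undershoot zero are clamped, with undershoots beyond 10×
the absolute tolerance logged as clamp events (default runs produce
none — the tests fail otherwise).  The first output row is the initial
condition exactly.  Tolerance halving changes 200 h endpoints by <0.1%,
and the tumour-only benchmark agrees with a fixed-step RK4 oracle
(dt = 0.01 h) to <0.1% and with the closed-form logistic solution to
<10⁻⁵ relative.

Initial conditions (not reported with the original simulations) default
to T₀ = 10⁴, E₀ = 10², R₀ = 10², M1₀ = M2₀ = 10³, F₀ = 10² cells and
zero for all signalling species.  Headline results are fold changes
versus the same-time control, which buffers them against this choice;
the calibration absorbs residual sensitivity.

## Calibration

Gains without published values are fitted by deterministic bounded
search on the objective Σ((achieved − target)/target)², computed by
re-simulation: bounded Brent for single-gain problems (robust on the
flat saturated branch of the dose response), bounded Nelder-Mead from
the bounds midpoint for joint fits; iteration cap 500, convergence at
objective < 10⁻⁶ or relative step < 10⁻⁸.  If the current values
already meet every target within tolerance (and lie inside the bounds),
calibration returns them unchanged with zero iterations — refitting a
converged fit is a fixed point.

* `kF_cape` (bounds [0, 1] h⁻¹, initial tabulated guess 10⁻³) is fitted
  so CAF(72 h, 100 μM) = 0.5× control → **0.026153 h⁻¹**.
* `gM1` ∈ [0, 0.05] h⁻¹, `gM2`, `gR` ∈ [0, 1] are fitted jointly to
  M1(72 h, 100 μM) = 1.5× and M2(72 h, 100 μM) = 0.5× control with a
  quadratic penalty on any dose-wise increase of Treg levels at 72 h →
  **gM1 = 0.005242 h⁻¹, gM2 = 0.158162, gR = 0.957574**.  The problem is
  under-determined (three gains, two targets plus a one-sided
  constraint); the shipped values are the deterministic optimiser's
  solution, not a unique identifiable point.

Whether the macrophage ±50% figures were themselves calibrated or
emergent in the original implementation is not stated; here they are
treated explicitly as calibration targets and labelled as such.

The recovery harness perturbs a fold-change target with seeded
lognormal noise (mean-preserving parameterisation) and refits.
Noiseless recovery is exact to <10⁻³ relative; at 5% relative noise and
20 replicates (seed 11) the Monte-Carlo RMSE of kF_cape is 2.0×10⁻³
with bias −4×10⁻⁴, and these values are pinned in the tests with ~2×
headroom.

## Synthetic ELISA plates and statistics

The plate generator emulates the structure of the marker assays
(CA 72-4 and decorin, 24/48 h, doses 0–200 μM, n = 8 per condition as in
the statistical analysis; the assay protocol itself reports n = 12 —
the generator default follows the statistics, configurable): seeded
lognormal replicates around control-normalised fold-change means with a
configurable coefficient of variation (default 10%).  The fixture table
anchors the printed values (CA 72-4 48 h/100 μM = 2.8×; decorin 24 h
plateau = 1.8×; decorin 48 h/100 μM = 3.5×); every other mean is a
synthetic monotone interpolation flagged as such in the file.  The
generator does not model plate effects, standard-curve (4PL)
calibration, heteroscedasticity beyond the lognormal's mean–variance
link, or inter-day drift — passing tests therefore validate the
statistical pathway, not the biology of the assays.

Welch's heteroscedastic one-way ANOVA, Games–Howell post hoc
(studentized-range with Welch–Satterthwaite df), Kruskal–Wallis with
midrank ties correction, and Dunn's test with Holm step-down are
implemented from their standard formulas rather than delegated, so each
is verified against hand-computed examples and cross-checked against
independent implementations (pingouin, scipy) in the tests.  Degenerate
inputs: a zero-variance group is an error for the Welch-type tests;
all-identical data yields H = 0 (p = 1) for Kruskal–Wallis.

## Problem sizes

All shipped experiments are desk-scale: ≤12-dimensional ODE systems over
200 h, dose scans of five doses, calibrations of ≤3 parameters (a few
hundred simulations), and 20-replicate recovery runs.  The full test
suite and the reproduction script each complete in well under a minute
per headline claim on one CPU.

## Known limitations

* Phenomenological throughout: gains map dose to effect without
  mechanistic kinetics; no pharmacokinetics, no spatial structure, no
  stochasticity.
* Several species named in the broader model family (glucose, CXCL12,
  checkpoint complexes, NF-κB, p53, the adipocyte axis, IL-6, CCL2,
  APC/IL-2, Th cells) have no dynamics or parameters and are not
  simulated; the extended tumour/effector form is evaluable only with
  user-supplied coefficients.
* The immunoregulation gains are not uniquely identifiable from the two
  macrophage targets; only the documented deterministic procedure makes
  the shipped values reproducible.
* Modular and coupled modes are different projections of the same
  parameter set and need not agree quantitatively.
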