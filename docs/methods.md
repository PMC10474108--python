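# Methods

## Scope and structure

`cleftqsp` simulates antibody-mediated interception of secreted tau and
α-synuclein (aSyn) in the synaptic cleft. Two blocks are coupled:

1. **Antibody exposure** (`pbpk`): analytic biexponential plasma
   disposition superposed over an i.v. bolus regimen; CSF and ISF antibody
   track plasma first-order (lag 24 h) toward fixed exposure ratios; the
   lumped cleft compartment exchanges with ISF by flow and is depleted by
   capture.
2. **Cleft dynamics** (`cleft`): per-species secretion, reversible binding
   to a shared postsynaptic acceptor pool, internalization, pinocytosis
   (tau monomer only), irreversible antibody capture, and first-order
   escape to ISF. Escaped protein drains ISF → CSF → clearance, making CSF
   and ISF biomarker levels model outputs rather than inputs.

Trials (`trials`) run paired treated/placebo integrations from the same
calibrated steady state; `sensitivity` re-runs trials along parameter
grids; `calibration` holds unit conversions, the secretion root-solve and
the in-vitro uptake fits; `fixtures` generates synthetic surrogates of the
calibration datasets; `config`/`cli` provide the JSON/command-line surface.
The two genuine fitting problems (plasma PK, in-vitro uptake) follow the
Model-object / fit() / Results-object convention; the simulator itself is
plain functions over frozen dataclasses.

## Compartment geometry and flows

| quantity | value | note |
|---|---|---|
| V_csf | 0.15 L | adult CSF volume |
| V_isf | 0.26 L | ~20% of brain volume |
| V_neuron | 0.76 L | 58% of brain volume |
| V_cleft_total | 0.001 L | 1e11 neurons × 1000 synapses × 1e-17 L |
| cleft width | 40 nm | with 0.1–1 µm² apposition → 4e-18–4e-17 L/synapse |
| Q_isf_cleft | 0.001 L/h | antibody access to the cleft; swept to 0.01 |
| Q_isf_csf | 0.0075 L/h | bulk ISF drainage carrying secreted protein |
| Q_csf_clear | 0.021 L/h | CSF turnover (≈0.35 mL/min production) |

Q_isf_csf and Q_csf_clear were set jointly so that the steady-state
ISF:CSF concentration ratio of any cleft-secreted protein is
Q_csf_clear/Q_isf_csf = 2.8. This single choice makes both measured pairs
emerge from one mechanism: calibrating CSF tau to 3 pM implies ISF tau
8.4 pM (microdialysis range 3.3–66 pM), and calibrating CSF aSyn to 112 pM
implies ISF aSyn 313.6 pM (range 44–620 pM). Protein re-entry from ISF into
the cleft is neglected: free cleft concentrations exceed ISF levels by
4–5 orders of magnitude.

## Antibody exposure

Plasma: two-phase disposition with central volume 3.1 L (plasma volume),
30% distribution phase of half-life 24 h, and the published terminal
half-life per antibody (range midpoints: gosuranemab 600 h, tilavonemab
765 h, semorinemab 400 h, cinpanemab 700 h, prasinezumab 260 h). One
parameterization is used for all five; per-antibody central volumes are not
identifiable from the published material, and the graded endpoints depend
on brain exposure only through the ratio windows below.

Brain entry: CSF/plasma 0.0025 and ISF/plasma 0.002, inside the published
windows (0.001–0.004 and 0.0007–0.003). A first-order ISF sink (futile
microglial FcγR binding) and a static tortuosity attenuation are available
and default to off/1.0 — the default ISF ratio already sits in the printed
window, which is how the published analysis folds those effects in.

Cleft antibody is a state: dA/dt = (Q/V_cleft)(A_isf − A) − Σ f_i^A T_i A.
Capture is irreversible (f_i^A = 0.001/Kd_i per min·nM, the published
convention) and consumes antibody stoichiometrically. This depletion is the
load-bearing nonlinearity: for gosuranemab in PSP, consumption by ~1.6 µM
free monomer holds cleft antibody near 20–30 pM (the published 20–50 pM
range) while ISF antibody is in the tens of nM; a fast-equilibrium
(non-depleting) mode is available for comparison.

## Cleft kinetics and the choices behind them

Parameters printed in the source material: receptor (acceptor) Kd of
oligomeric tau 0.3 nM (PSP) and 40 nM (AD), monomeric tau 60 nM (LRP1),
PFF aSyn 800 nM; acceptor density R̄ = 10 µM; antibody Kd/half-life per
Table; CSF levels and oligomer fractions. Everything else (on-rates,
internalization rates, cleft residence half-lives, pinocytosis pool) lives
only in supplementary material and was fixed here, once, by calibrating
against published *non-graded* simulation outputs (the tilavonemab 4000 mg
uptake-reduction, the gosuranemab monomer cleft effect and cleft antibody
level, the cinpanemab 1250/8100 mg and prasinezumab 8100 mg reductions, the
AD-parameterization reductions). The graded endpoints were not used in this
calibration and are genuine out-of-sample predictions.

Two structural decisions matter most:

* **The oligomer:monomer ratio applies to secretion.** S_1 is a fixed
  fraction of S_0 (tau 1:100, aSyn 0.275). For aSyn, whose species share
  kinetics, the free-level ratio is then 25–30% in every compartment, as
  measured. For tau, enforcing 100:1 on free *cleft* levels instead would
  put ~16 nM of oligomer against a 0.3 nM receptor Kd, saturating the
  acceptor pool; a saturated pool buffers the uptake flux (zeroth-order in
  free oligomer) and makes uptake insensitive to receptor affinity,
  contradicting the published affinity sweep in which loosening the PSP
  oligomer Kd from 0.3 to 1600 nM raises the antibody effect from <1% to
  ~35%.
* **Monomer and oligomer use different kinetic regimes on the shared
  pool.** Monomeric tau associates slowly with internalization-competent
  sites (f_0^R = 5.1e-6 /(nM·h)) but is absorbed quickly once bound
  (a_0 = 0.5 /h): its uptake is association-limited, and the µM-scale free
  monomer occupies almost none of the pool. Multivalent oligomer binds
  avidly at the printed Kd (f_1^R = 0.36 /(nM·h) ≈ 1e5 /(M·s)) and
  internalizes slowly (a_1 = 3.6e-3 /h ≪ b_1), so its uptake is
  quasi-equilibrium and scales as R̄·a_1/Kd — which is exactly what makes
  receptor-affinity sensitivity behave as published.

Remaining defaults: recovery r = 1 /h; cleft residence half-life H =
18000 h for tau (free cleft tau 1.64 µM ≈ 10 molecules/synapse at
1e-17 L, within the published 5–20) and 13.7 h for aSyn; aSyn
internalization a = 0.02 /h both species; pinocytosis pool P̄ = 1 µM,
f_0^P = 2e-5 /(nM·h), a_0^P = 0.1 /h (~25% of monomer uptake at baseline);
intraneuronal degradation k_deg defaults to 0, so cumulative internalized
protein equals the time-integral (AUC) of the uptake rate and the
cumulative and AUC reduction metrics are directly comparable. An optional
extra extracellular degradation rate exists and defaults to 0.

## Calibration and fitting

`calibrate_secretion` root-finds log S_0 (secant on the smooth, monotone
log-CSF map; each evaluation is a steady-state solve by long-horizon stiff
integration plus Newton polish, residual < 1e-12 of the secretion scale)
until steady-state free CSF monomer matches the clinical target within
0.1%; S_1 follows from the secretion fraction. Calibrations are cached per
(disease, geometry).

`UptakeModel` fits the reduced bath model — constant extracellular
concentration (excess-volume culture), no secretion — to uptake data by
log-parameter least squares: dose–response at a 1 h endpoint for PFF aSyn
(recovers Kd and a), multi-concentration time courses for the tau modes
(recovers on-rate, internalization and the pinocytosis pair; a
proportionality constant links internalized amount to signal and is
reported, not interpreted). `PlasmaPKModel` fits the biexponential on
log-concentration. All fits are exercised as parameter-recovery problems
against `fixtures`, which generates synthetic datasets from known truth:
exact recovery on noiseless data, graceful degradation under 10% lognormal
noise (plasma half-life within ~15%, PFF Kd within ~15% per seed).

The synthetic datasets reproduce the *structure* of the real calibration
inputs (dose panels, sampling times, assay endpoints), not their values;
passing recovery tests therefore demonstrates identifiability of the
fitting pipeline, not agreement with any laboratory measurement.

## Trials, metrics, numerics

A trial integrates 20 coupled states (cleft block, ISF/CSF antibody,
ISF/CSF protein) piecewise between dose times with LSODA (BDF fallback),
rtol 1e-8, atol 1e-12 nM, from the calibrated baseline; the placebo arm is
integrated identically with zero dose. Metrics: per-compartment,
per-species maximal target engagement TE = 1 − free/baseline (clipped to
[0,1]); cumulative uptake reduction 1 − C_1,treated(T)/C_1,placebo(T); the
time-averaged variant 1 − ∫C_1,t dt / ∫C_1,p dt; and the maximal
instantaneous uptake-rate reduction. Standard runs use 800 output points
over 52 weeks (13 Q4W doses; ~6 s per trial on one CPU); refining solver
tolerances 10× moves endpoints by <0.1%. Sweeps over receptor parameters
re-calibrate secretion per point by default (for oligomer-Kd sweeps this is
provably a no-op, since S_1 is slaved to the unaffected monomer side — the
suite asserts it); antibody-parameter sweeps never re-calibrate.

## Known limitations

* The printed source is not fully self-consistent; where statements
  conflict the model follows the majority of quantitative anchors. Two
  consequences are visible in the acceptance suite: the tilavonemab
  hypothetical high-dose endpoint and the 100-fold antibody-affinity
  degradation scenario are reproduced only to within the ambiguity of the
  conflicting printed statements.
* One exposure parameterization serves all five antibodies; per-antibody
  brain-penetration differences beyond half-life are not represented.
* No intraneuronal aggregation, microglial biology, extracellular-vesicle
  shuttling, spatial diffusion within the cleft, or translation of uptake
  to clinical scales. Uptake of oligomer into the postsynaptic neuron is
  the terminal readout and stands proxy for propagation.
* The cleft residence half-lives are effective lumped parameters (matrix
  binding, recapture, nanocolumn geometry), not literal diffusion times;
  they should be reinterpreted before using the model outside the
  calibrated regimes.
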