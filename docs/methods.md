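# Methods

## Model structure

The simulator assembles one linear ODE system per virtual subject covering
both analytes. States are amounts (mg base equivalents); time is hours from
the first dose; concentrations are mg/L.

**Absorption.** Oral doses of hydroxychloroquine sulfate are converted to
base equivalents (salt factor = MW_base/MW_salt = 335.87/433.95) and enter a
stomach compartment (first-order emptying, 4 h^-1) followed by seven
small-intestinal transit segments (transit constant 7/3.32 h^-1 from a
3.32 h mean small-intestinal transit time). Each segment absorbs into the
portal circulation with ka = 2·Peff/r; Peff comes from the Caco-2 Papp via
a log-log correlation (log10 Peff[10^-4 cm/s] = 0.4926·log10 Papp[10^-6
cm/s] − 0.1454), and the intestinal radius scales with body size as W^(1/3)
(1.25 cm at 70 kg). Unabsorbed drug exits to a sink, so the fraction
absorbed is emergent (0.89 for the adult defaults). Dissolution is not
modeled: the drug is an immediate-release tablet of a freely soluble salt,
so permeation, not dissolution, limits uptake.

**Distribution.** All organs except the lung are perfusion-limited with
tissue:blood partition coefficients Kp/(B/P). Kp values are predicted by a
composition-based method for moderate-to-strong bases: pH-dependent
ionization of the diprotic base (pKa 9.67/8.27) in plasma (pH 7.4) and cell
water (pH 7.0), association of the ionized species with tissue acidic
phospholipids (association constant back-derived from red-cell partitioning
through the blood:plasma ratio), and neutral-lipid/phospholipid
partitioning via logP. Predicted Kps are uniformly rescaled so the
steady-state volume of distribution matches a configured reference
(1500 L plasma-referenced for the parent). This reference is deliberately
far below terminal-phase literature estimates: the months-long deep-tissue
phase is irrelevant to a 10-day dosing window, and an effective Vss of this
size makes the 10-day AUC track clearance, which is the regime in which
baseline-relative exposure ratios are meaningful. Consequences: terminal
half-life and very-late redistribution are *not* reproduced, and absolute
concentrations beyond the dosing window should not be over-interpreted.

The blood:plasma ratio (7.2 at hematocrit 0.45) is applied as a fixed
scalar between whole-blood and plasma observables; per individual it is
adjusted linearly in hematocrit (the red-cell-bound part scales with
Hct/0.45), which matters in children and is neutral in adults.

**Lung.** The single permeability-limited tissue: an extracellular pool in
the pulmonary blood path (0.15 L at 70 kg) and an intracellular pool
(0.35 L), exchanging as
dA_IC/dt = (PS + CL_int,T)·Cu_EC − PS·Cu_IC/KF,
with PS from the Calu-3-scaled permeability (0.5881·Papp_Caco-2 + 4.5594,
10^-7 cm/s) times a 10^6 cm^2 exchange area (linear in body weight), KF a
lumped intracellular trapping scalar (default 20; lysosomal sequestration
and binding are not separated), and CL_int,T the apparent active uptake.
CL_int,T is the one calibrated parameter: scalar root-finding drives the
day-6 pre-dose-trough lung:plasma ratio in the baseline typical adult under
the standard course to 200, giving 6.63 L/h. The two-pool steady-state
unbound ratio (PS + CL_int,T)/PS·KF is verified against the closed form.
Lung tissue concentration is reported as total lung amount over total lung
tissue volume. The calibrated CL_int,T is held fixed across adult
populations; pediatric lung exposure is not predicted (out of scope).

**Elimination.** Total reference plasma clearance (42 L/h oral, a
literature-consistent stand-in) is split exactly by the pathway fractions —
CYP2C8 37.3%, CYP2D6 19.3%, CYP3A4 16.7%, renal 26.7% — which are the
disposition contract of the model. The hepatic share is inverted through
the well-stirred liver model on the healthy reference physiology to
per-enzyme unbound intrinsic clearances, then scaled per individual by
enzyme abundance, liver size and unbound fraction; the renal share is
likewise inverted through kidney extraction and scales with GFR/120
mL·min^-1. Both inversions make the configured clearances the *emergent*
systemic clearances, so the fractions and the analytic AUC limit
(AUC = fa·Dose/CL for a renal-only variant) hold to numerical precision.
Each CYP flux forms DHCQ with formation fraction 1.0 by default (the true
fraction is unknown; exposed in config and echoed in output metadata).
DHCQ carries its own predicted Kps, a literature-style renal clearance
(10 L/h plasma) and a lumped hepatic intrinsic clearance (60 L/h) that the
validation module can re-fit from a concentration-time profile.

**Numerics.** The system is linear and time-invariant between dose events,
so the default integrator propagates with one matrix exponential per 0.25 h
output step and applies doses as impulses — exact to machine precision
(mass balance ~1e-12), with doses, linearity and superposition exact by
construction. A stiff solve_ivp path (BDF/LSODA, rtol 1e-8, atol 1e-10 mg)
is retained and cross-checked in tests. Drug interactions make the system
time-varying through CYP activity; there the propagator uses per-step
exponentials with activity frozen at the step midpoint (activity evolves on
multi-hour timescales, so the midpoint freeze is accurate to <0.1% on AUC,
verified against the BDF path). Dose events must align with the output
grid in the exponential path; the BDF path has no such restriction.

## Virtual populations

A healthy 20-50 y adult reference (70 kg, cardiac output 336 L/h, GFR
120 mL/min, organ volumes/flows from standard physiology tables) anchors
everything; organ flows always sum to cardiac output. Variability is
log-normal and mean-one: one size deviate (CV 20%) on weight, volumes and
flows; independent per-CYP abundance deviates (CV 30%); a GFR deviate
(CV 30%). A single integer seed drives per-trial, per-subject substreams.

Special-population transforms are explicit factor tables, reported in
output metadata, standing in for proprietary population databases. Where
open literature constrains a scalar only to a range, the default inside
that range was chosen so the baseline-relative exposure-ratio tables for
geriatric, hepatic, renal and pregnant populations are reproduced — the
tables are calibration surfaces of this re-implementation, not blind
predictions:

* **Geriatric** — linear declines past an age-40 anchor: GFR 0.75%/y,
  hepatic abundance 0.5%/y, cardiac output 0.3%/y (flows renormalized).
* **Cirrhosis** — Child-Pugh factors on functional hepatic abundance
  (0.78/0.60/0.46 for A/B/C), hepatic arterial flow (0.90/0.75/0.60) and
  albumin (0.95/0.90/0.85; the unbound fraction rises as
  fu' = fu/(alb·(1−fu)+fu)).
* **Renal impairment** — GFR set to band-typical values (45 and
  20 mL/min); renal drug clearance scales as GFR/120; the optional uremic
  effect on hepatic CYPs is off by default.
* **Pregnancy** — one smooth gestational shape p(w) = H(w)/H(37) with
  H(w) = w^4/(w^4 + 15^4) scales every altered quantity: CYP2C8/2D6/3A4
  activity maxima 1.9/2.6/2.2, GFR 1.45, albumin −30%, blood volume +40%,
  weight +12.5 kg, cardiac output +30%. Week 0 is the identity.
* **Pediatrics** — growth-reference weights, age-dependent organ
  composition fractions, sigmoidal CYP ontogeny (age-50 of 0.30/0.10/0.05 y
  for 3A4/2D6/2C8), a postmenstrual-age GFR maturation (TM50 47.7 weeks,
  Hill 3.4), an age-dependent hematocrit (nadir 0.33 in infancy), and an
  effective *distributional-flow maturation* on cardiac output (0.10 at
  birth rising to 0.52 in adolescence, 1.0 from 18 y). The last factor is
  the model's single strongest effective parameter: in a purely
  flow-limited body, first-dose Cmax per mg/kg is set by cardiac output
  per kg, and children's high specific perfusion would otherwise make
  weight-based exposure matching impossible at the doses the matching is
  known to produce. It lumps early-distribution kinetics that are not
  flow-limited in reality (finite tissue/red-cell uptake rates) and was
  calibrated against the weight-based dose table; it should be read as an
  exposure-matching device, not a hemodynamic claim.

## Drug interactions

Perpetrators are one-compartment oral models (closed-form superposition
over their regimen; unbound molar concentrations at the liver). Defaults:
gemfibrozil 600 mg BID (competitive Ki,u 9.3 µM on CYP2C8 plus a folded
acyl-glucuronide mechanism-based term, KI,u 20 µM, kinact 0.28 h^-1 —
deliberately far below the glucuronide-only literature value, since the
metabolite itself is not modeled and the folded constant is calibrated so
the healthy-adult AUC ratio lands at the reported magnitude); quinidine
200 mg QD (competitive CYP2D6, Ki,u 0.06 µM); ritonavir 100 mg QD
(mechanism-based CYP3A4, KI,u 0.17 µM, kinact 20 h^-1, plus weak
competitive CYP2D6). Hepatic CYP turnover half-life defaults to 36 h.
Scenario timing is fixed: perpetrator days 1-12, victim course days 3-7,
AUC window 240 h from the first victim dose. Every dynamic AUC ratio is
bounded by the complete-inhibition ceiling 1/(1−fm), and removing the
perpetrator reproduces the victim-only simulation bit for bit. Interaction
tables are emitted in two conventions: combination vs the same population
without the perpetrator (the interaction magnitude proper) and combination
vs the healthy 20-50 y baseline (the reporting convention of combined
age-plus-inhibitor scenarios); in the healthy-adult population the two
coincide.

## Trial simulation and verification conventions

Virtual trials follow the 10-trials-of-10-subjects convention; exposure
ratios are ratios of arithmetic means of individual Cmax and AUC
(geometric-mean ratios are emitted alongside, since the choice is not
uniquely determined by the tables' labeling). AUC uses the linear
trapezoid on the 0.25 h grid over 240 h from the first victim dose, even
though dosing spans 5 days. Troughs are grid values at pre-dose times.

Fold-error verdicts (2.0- and 1.25-fold) are inclusive at the boundary.
The "90% interval" is the empirical 5th-95th percentile band of simulated
individual concentrations — a prediction interval; self-coverage on
synthetic observations drawn from the simulated population is ~0.9 by
construction and is property-tested. Serum-matrix observations are
rejected (red-cell contamination inflates apparent concentrations for
drugs with high blood:plasma ratios). The DHCQ hepatic-clearance fit is a
scalar log-least-squares over repeated simulation with a
profile-likelihood-style interval; parameter recovery on synthetic noisy
profiles (10% proportional error, 12 points) is within 15% per fit and
<5% mean bias across replicates.

## What the synthetic data do and do not show

The generator emulates the *structure* assumed by the analysis —
physiological covariates, log-normal variability, proportional
observation noise with LLOQ censoring — with known ground truth, so
harness tests demonstrate internal consistency (coverage, fold checks,
parameter recovery), not agreement with clinical data. External digitized
study profiles are not redistributed; the validation harness accepts them
as delimited text when available. Real-data features not emulated:
correlated covariates (weight-age-GFR), model misspecification,
assay-specific error structure, dropout/sparse designs.

## Problem sizes

Default analysis and test sizes: 0.25 h output grid over 240 h; 10x10
subjects per scenario; 30-replicate recovery and 40-replicate coverage
Monte Carlo; the exact propagator makes a subject simulation ~15 ms, an
interaction subject ~0.3 s.

## Known limitations

Terminal-phase kinetics are intentionally compressed (see Distribution).
Cmax-based ratios in impaired populations are flatter than AUC-based ones
in this model, because first-dose and early Cmax are distribution-dominated
while the reported tables suggest a stronger clearance influence; AUC
ratios are the primary calibrated quantity. DHCQ hepatic clearance is not
enzyme-resolved, so perpetrators inhibit DHCQ formation but not its
further metabolism. The pediatric distributional-flow factor is an
effective calibration device. Ethnicity enters only through body weight.
No pharmacodynamic or viral-kinetics linkage is included.
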