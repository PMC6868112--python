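# Methods

## The model

The glucagon challenge test is a 6 h protocol: 3 h of undisturbed baseline,
then 3 h in which somatostatin shuts off endogenous pancreatic secretion
while glucose, insulin and glucagon are infused at constant rates — insulin
to hold its baseline, glucagon to rise 2–3-fold above it.  The model has
three blood compartments with concentrations G (glucose, g/L), I (insulin,
mU/L) and E (glucagon, pmol/L), coupled one-way to the surface kinetics of
the glucagon receptor on a representative hepatocyte.

Receptor state is tracked as dimensionless fractions of the conserved
total: free `r`, glucagon-bound `r_e`, internalized `r_i = 1 − r − r_e`.
Binding is driven by the hepatic interstitial glucagon amount
`E_h = V_h·E` at rate `k_on`; the bound form dissociates (`k_off`) or
internalizes (`k_in`); internalized receptor recycles (`k_rec`); free
receptor may internalize at `k_in_free` (zero by default).  For constant E
the subsystem has a unique attracting steady state in closed form, used
both as the phase-1 state and as the estimator's baseline constraint.

Hepatic glucose production responds to the bound fraction through a Hill
function with coefficient n = 2,

    F_hgp(r_e) = b_G + V_1 · r_e² / (K'1² + r_e²),

where `K'1 = K1 / R_tot` is the identifiable surrogate for the total
receptor number (K1 and R_tot are separately unidentifiable; the package
refuses configurations that try to free both).  Glucose is cleared by an
insulin-independent route `V_ii·G/(K_ii+G)` (with `K_ii = 0` by default the
term is the constant `V_ii` for positive glucose, and non-positive glucose
is rejected rather than floored) and an insulin-dependent route
`V_id·I·G/(K_id+G)`.  During the clamped phase the hormone equations
decouple and are exactly exponential,
`C(t) = C∞ + (C̄ − C∞)·e^{−k_deg (t−3)}` with plateau `C∞ = Q/(V·k_deg)`.

Internal time is hours on [0, 6] with the infusion switch at t = 3 h;
observation files carry minutes and are converted at the I/O boundary.
Two printed values circulate for the glucagon distribution volume (9.6 and
19.6 L); the package defaults to 19.6 L, the only value that produces the
designed 2–3-fold glucagon rise given `k_degE ≈ 5.7 /h` (the default gives
a plateau of 36.8 pmol/L, a 2.6-fold rise over the basal 14.3 pmol/L).
The maximal rates `V_1`, `V_ii` carry units g/L/h (and `V_id`
(g/L/h)/(mU/L)): the terms they multiply are dimensionless or insulin
concentrations, so these are the only dimensionally consistent units even
though some published tables print 1/h.

### Baseline constraints

The first 3 h are a steady state: basal secretion balances hormone
clearance (`F̄_I = k_degI·Ī`, `F̄_E = k_degE·Ē` — derived, never free), the
receptor pair sits at its closed-form steady state, and production balances
clearance in the glucose equation:

    F̄_hgp = b_G + V_1·h(r̄_e) = V_ii·Ḡ/(K_ii+Ḡ) + V_id·Ī·Ḡ/(K_id+Ḡ).

These two relations eliminate `b_G` and `V_ii` given the other parameters,
so every candidate parameter vector during estimation — and the returned
estimate — satisfies the baseline balance exactly by construction.
Negative eliminated values are reported with a warning rather than an
error: optimizers must be able to traverse such iterates, and a soft
positivity penalty (weight 10 per basal unit) steers final estimates back
to the physical region.

## Forward simulation

Phase 1 is represented as the constant baseline (it is a steady state by
design, and the basal secretion rates play no role after the switch).
Phase 2 integrates the five-state system with LSODA at rtol 1e−9: the
receptor block mixes rates from 0.18 /h (recycling) to ~36 /h
(dissociation + internalization), so an adaptive stiff-capable integrator
at tight tolerance is required for the fixed-point and conservation
oracles to hold to 1e−6 and better.  Disposal `Rd(t)` and production
`F_hgp(t)` are emitted as model channels directly, standing in for the
isotope-tracer-derived rates of the clinical protocol.

## Synthetic cohorts

A cohort draws per-subject parameters from independent truncated normals
with the published cohort means and SDs (V_1 5.63 ± 1.97, K'1 0.00501 ±
0.00257, V_id 1.52 ± 0.963, K_id 11 ± 6.62, k_degI 30.5 ± 8.27, k_degE
5.73 ± 1.84, k_in 21.5 ± 15.2, V_h 4.65 ± 2.28, b_G 0.0804 ± 0.228), basal
glucose 0.9 ± 0.045 g/L and insulin 10 ± 1 mU/L (the insulin clamp plateau
480/(1.52·30.5) ≈ 10.35 mU/L sits at the basal level, honoring the clamp
design) and basal glucagon fixed at the physiological 14.3 pmol/L.

Two joint rejection rules keep draws consistent with the study:

* the eliminated `V_ii` must be positive (baseline balance must hold);
* the baseline Hill occupancy `r̄_e²/(K'1²+r̄_e²)` must be below one half.
  Independent draws otherwise put nearly half the subjects in a
  baseline-saturated regime in which receptor loss *widens* the response
  range — such subjects could not have shown the challenge response (and
  its reduction under treatment) that defines the test.  The
  cohort-average regime has occupancy ≈ 0.35.

The treatment multiplies K'1 by 0.0109/0.00501 ≈ 2.18 (the cohort-average
after/before ratio; receptor number roughly halved).  The after-visit
keeps the subject's baseline state, basal HGP and clearance traits, and
re-balances the basal production through `b_G` (the Hill term at baseline
drops when K'1 rises, and `b_G` absorbs the difference).  This is the only
way to hold the visit self-consistent without making `V_ii` negative, and
it reproduces a feature of the clinical fits, where `b_G` inflates by an
order of magnitude for some after-treatment subjects.  A consequence worth
knowing when interpreting cohort comparisons on synthetic data: the
synthetic `b_G` (and to a lesser degree `V_1`) carries a systematic
before/after difference that the real cohort showed only weakly.

Observation noise is multiplicative Gaussian, `value·(1 + CV·z)`,
independent across channels and times: CV 5% for glucose, 10% for the
hormones and the tracer-derived rates (assay-like proportional errors;
positive channels at these CVs).  Whether the clinical F_hgp/Rd channels
carry errors correlated with glucose is unknowable from published
information; independence is assumed.  Identical seeds reproduce cohorts
bit-for-bit.

## Parameter estimation (smooth profiling)

Per record, in stages:

1. **Baselines** — Ḡ, Ī, Ē, F̄_hgp are phase-1 sample means; r̄, r̄_e come
   from the closed-form steady state at the current kinetics (so they move
   with k_in, V_h during the outer search).
2. **Hormone clearances** — k_degI, k_degE by least squares on the exact
   exponential solutions (the hormone block decouples one-way, so this
   equals profiling them but is exact and well conditioned).  A fit whose
   plateau coincides with its baseline carries no decay information and is
   flagged weakly identified.
3. **Pre-fit** — (V_id, K_id) from the disposal channel under the baseline
   balance, then (V_1, K'1, k_in, V_h) from the production channel with
   the receptor ODE solved exactly.  The production-channel problem is
   nonconvex (a sticky spurious basin sits on the b_G = 0 boundary), so
   this fit runs a deterministic multistart over scalings of the weakly
   identified (K'1, k_in, V_h) block and keeps the best run; the breadth
   is configurable (3 starts by default, 11 in the validation
   configuration).  This stage supplies the robustness a λ-continuation
   is usually asked for: it lands any starting guess (tested from 2×
   truth) in the basin of the profiling optimum.
4. **Profiling** — latent states (G, r, r_e) are cubic B-splines on
   [3, 6] h with knots at observation times plus midpoints, extra knots
   graded geometrically into the first interval (the bound receptor
   relaxes at k_off + k_in ≈ 36 /h, a boundary layer much narrower than
   the 15-min grid), and optional global subdivisions.  The inner problem
   minimizes the weighted channel misfit plus λ times the 5-point
   Gauss–Legendre quadrature of the squared ODE residual, over spline
   coefficients, by Levenberg–Marquardt with an analytic Jacobian.  The
   initial condition at the switch is enforced exactly by fixing the first
   coefficient of each state (at a fully clamped left end the first basis
   function is the only one alive).  The outer problem minimizes the pure
   data misfit of the inner solution over log-parameters
   (trust-region least squares by default; Nelder–Mead available),
   warm-starting the inner solver.

Channel weights default to inverse squared basal levels (glucose,
production, disposal on comparable relative scales).  Penalty weights
normalize each equation by state scale × relaxation rate so the fast
bound-receptor equation is not over-weighted.  The λ schedule defaults to
the single stage λ = 1e4: weakly penalized stages are under-determined for
this model (many parameter vectors reach near-zero misfit when the spline
is barely tied to the dynamics) and continuation through them actively
harms the fit, while the pre-fit already provides global robustness.  Any
increasing schedule remains expressible.

### Regularization and identifiability

The receptor/Hill block is *sloppy*: at the study's design (12 phase-2
samples per channel) the weighted sensitivity matrix at the cohort-average
subject has singular values spanning ~59 to ~0.22, with soft directions
mixing (K'1, k_in, V_h) and (V_id, K_id).  The Cramér–Rao bound for
log K'1 from one visit is ≈ 1.5 at the default noise (≈ 1.0 with 5% noise
on every channel): no per-visit estimator can pin K'1 to tens of percent
at this noise, and unregularized fits escape along the ridges to absurd
values.  The estimator therefore applies a unit log-normal ridge toward
the published population means (empirical-Bayes shrinkage; weight 1 per
log-parameter, configurable).  Shrinkage rescales signal and noise
together along each direction, so it tames ridge escapes without changing
the detectability of paired differences in the linear regime.

For validation studies on noiseless data the appropriate configuration is
no ridge and one extra knot subdivision (`ridge_weight=0,
extra_subdivisions=1`): the default knot spacing leaves a λ-independent
discretization bias of up to ~8% in the soft directions, halving the
spacing removes it, and with clean data no prior is wanted.  This mirrors
the method's own doctrine that the smoothing controls are tuned per fit.
With that configuration the estimator recovers all six free parameters of
drawn subjects to better than 1% from noiseless records, from starting
guesses as poor as 2× truth.

The practical consequence for the paired study design: at 5–10% assay
noise the per-visit K'1 estimates carry order-one log-scale uncertainty,
so an eight-subject paired cohort detects the treatment-induced K'1
doubling only sporadically, and part of the signal surfaces in V_1
instead (the best-determined direction; the clinical analysis likewise
found V_1 closest to significance after K'1 and the glucose peak).  The
acceptance suite states the target detection power and reports the
achieved rate honestly; the observed glucose peak G_max, which is measured
directly rather than estimated, detects the treatment far more reliably.

## Before/after statistics

The exact two-sided Wilcoxon signed-rank test enumerates the permutation
null over all 2^n sign assignments (integer convolution over doubled
midranks; zero differences dropped; two-sided p as the null mass at least
as far from the symmetric centre as observed).  Exactness matters: the
extremal eight-pair p-value 2/256 = 0.0078125 is unreachable by the normal
approximation.  BH adjustment is the standard step-up procedure applied to
unrounded p-values across all compared parameters jointly (11 columns:
ten fitted constants plus the observed glucose peak).  The receptor-number
change is

    Δ = (1/K'1_after − 1/K'1_before) / (1/K'1_before),

negative when receptors are lost (the published worked example
0.005 → 0.011 gives −0.55, a 55% decrease), reported both as the mean of
per-subject values and as the Δ of cohort-mean K'1.

## Problem sizes

Test and acceptance runs use seeded cohorts of 8 subjects × 2 visits; the
parameter-recovery checks use 3 noiseless subjects in the validation
configuration; the paired-detection estimate uses 6 (test suite) or 8
(acceptance script) cohorts at 5% noise on every channel; property oracles
use 20 random parameter draws.  All randomness flows from explicit seeds.

## Known limitations

* The somatostatin shutdown transient (3–4 min) is idealized to an
  instantaneous switch, as in the source analysis.
* F_hgp and Rd are emitted directly from the model; no tracer-kinetics
  simulation stands behind them, and their noise is assumed independent.
* Estimation is strictly per subject and per visit; no mixed-effects
  layer.
* The Hill coefficient is fixed at 2 and never estimated.
* Passing recovery tests on synthetic data shows the estimator inverts the
  model it simulates; it cannot show that the model captures features of
  real challenge-test data beyond those built in here.
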