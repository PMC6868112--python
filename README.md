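# glucagon-challenge

Modelling and analysis of the **glucagon challenge test** — a 6 h clinical
protocol in which, after a 3 h baseline, somatostatin shuts off endogenous
pancreatic secretion while insulin is clamped at its basal level and
glucagon is infused to 2–3× its basal level, isolating the effect of
glucagon on hepatic glucose production (HGP).  The package is aimed at
pharmacometricians studying drugs that change the number of hepatic
glucagon receptors (e.g. antisense antagonists), and at methodologists
interested in ODE parameter estimation by generalized profiling.

## The model

Blood glucose G (g/L), insulin I (mU/L) and glucagon E (pmol/L) follow
turnover equations; glucose production is driven by the glucagon-bound
fraction r_e of a conserved receptor pool on the hepatocyte membrane
(free r, bound r_e, internalized r_i = 1 − r − r_e):

    dG/dt  = Q_G/V_G + F_hgp(r_e) − V_ii·G/(K_ii+G) − V_id·I·G/(K_id+G)
    dI/dt  = Q_I/V_I − k_degI·I
    dE/dt  = Q_E/V_E − k_degE·E
    dr/dt  = −k_on·V_h·E·r + k_off·r_e − k'_in·r + k_rec·(1 − r − r_e)
    dr_e/dt =  k_on·V_h·E·r − k_off·r_e − k_in·r_e

    F_hgp(r_e) = b_G + V_1 · r_e² / (K'1² + r_e²)

K'1 = K1/R_tot is the identifiable surrogate for the total receptor
number: a drug that halves the receptor pool doubles K'1.  During the
clamped phase the hormone equations decouple and are exactly exponential;
during the baseline the whole system sits at a steady state that the
estimator enforces as an exact constraint (eliminating b_G and V_ii).

The package provides

* `model` — equations, closed-form receptor steady state, exact hormone
  solutions, baseline constraint elimination;
* `cohort` — a stiff forward simulator and a seeded generator of paired
  (before/after treatment) synthetic cohorts with the study's design:
  8 subjects, 16 samples at 135–360 min, treatment multiplying K'1 by
  ≈2.18, multiplicative assay noise;
* `profiling` — smooth (generalized) profiling estimation: penalized
  B-spline collocation inner problem, parameter outer problem, exact-ODE
  pre-fit, steady-state constraints enforced throughout;
* `stats` — exact Wilcoxon signed-rank (full enumeration), BH FDR,
  receptor-change Δ, cohort summary tables;
* `cli` — `glucagon-challenge simulate | fit | compare | run-all`.

## Worked example

```python
import numpy as np
from glucagon_challenge import (
    FixedKinetics, SubjectParameters, apply_baseline_constraints,
    make_baseline, simulate_subject, wilcoxon_exact, delta_receptor)

fixed = FixedKinetics()                      # k_on, k_off, k_rec from the literature
params = SubjectParameters()                 # cohort-average kinetic constants
baseline = make_baseline(G_bar=0.9, I_bar=10.0, E_bar=14.3, params=params,
                         fixed=fixed)
params = apply_baseline_constraints(params, baseline, fixed)

traj = simulate_subject(params, baseline=baseline)
t = np.linspace(3.0, 6.0, 300)
s = traj.sample(t)
print(f"basal HGP rate      : {baseline.Fhgp_bar:.3f} g/h/L")
print(f"glucagon plateau    : {s['glucagon'].max():.1f} pmol/L "
      f"({s['glucagon'].max() / baseline.E_bar:.2f}-fold rise)")
print(f"glucose peak        : {s['glucose'].max():.2f} g/L "
      f"at t = {t[np.argmax(s['glucose'])]:.2f} h")
print(f"bound-receptor peak : {s['r_e'].max():.4f} (baseline {baseline.re_bar:.4f})")
p = wilcoxon_exact(np.arange(8.0), np.arange(8.0) + 1.0)
print(f"extremal 8-pair Wilcoxon p : {p:.5f}")
print(f"receptor change for K'1 0.005 -> 0.011 : {delta_receptor(0.005, 0.011):+.2f}")
```

prints

```
basal HGP rate      : 2.066 g/h/L
glucagon plateau    : 36.8 pmol/L (2.57-fold rise)
glucose peak        : 2.47 g/L at t = 5.26 h
bound-receptor peak : 0.0085 (baseline 0.0037)
extremal 8-pair Wilcoxon p : 0.00781
receptor change for K'1 0.005 -> 0.011 : -0.55
```

The glucagon clamp
plateaus at Q_E/(V_E·k_degE) ≈ 36.8 pmol/L, a 2.6-fold rise over the
basal 14.3 pmol/L; glucose peaks mid-challenge and then declines as bound
receptor internalizes (the tolerance effect); eight concordant paired
differences give the exact signed-rank p-value 2/256 = 0.00781; and
cohort-average K'1 moving from 0.005 to 0.011 corresponds to a 55%
receptor loss (Δ = −0.55).

End-to-end from a shell:

```
glucagon-challenge run-all --seed 1 --out runs/demo
```

writes per-subject record CSVs with ground truth, fitted parameter tables
for both visits, and a comparison table with exact Wilcoxon p-values, BH
FDR and both Δ computations.

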