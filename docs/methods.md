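# Methods

## The clinical question and the estimand

During controlled mechanical ventilation, a lung recruitment maneuver
(LRM; here CPAP of 30 cm H₂O for 30 s) transiently raises intrathoracic
pressure and reduces venous return, so preload-dependent patients show a
larger transient fall in stroke volume — and, because the pulse-oximetry
perfusion index (PI) tracks stroke volume when vasomotor tone is stable,
a larger fall in PI.  The package evaluates relative hemodynamic changes
around an LRM as *diagnostic tests* for fluid responsiveness, defined as
a stroke-volume rise of at least 10% after a 250 mL crystalloid bolus
given over 10 min (volume expansion, VE).

For a variable x measured at T1 (before LRM) and T2 (after LRM), the
decrease-form change is Δx_LRM = (x_T1 − x_T2)/x_T1 × 100; the variation
indices (PPV, SVV, PVI), which rise during the maneuver, use the
increase form (x_T2 − x_T1)/x_T1 × 100, as do the VE changes over
T3 → T4.  The responder boundary is inclusive (Δsv_VE ≥ 10% responds);
the protocol's baseline-return rule (PI and SV back within 10% of
baseline before VE) is strict (<10%).

## Diagnostic evaluation

* **ROC/AUC.** The empirical AUC is the Mann–Whitney pair statistic,
  ties counting one half.  Inference is DeLong's structural-components
  method (midranks for ties): the variance of the AUC is
  var(V₁₀)/m + var(V₀₁)/n from the per-subject placement values, giving
  a normal-approximation CI truncated to [0, 1]; paired comparisons use
  the covariance of the two markers' placements.  DeLong was chosen
  because it is the standard nonparametric choice and needs no
  distributional assumption; the implementation is cross-checked in the
  test suite against R's pROC on a frozen fixture.
* **Cutoff.** The Youden index J = Sn + Sp − 1 is scanned over the
  midpoints between adjacent distinct marker values plus ±∞ sentinels;
  ties in J break toward the cutoff with higher sensitivity.  Reported
  cutoffs carry "test-positive iff marker ≥ cutoff" semantics.
* **Metrics at a cutoff.** Sensitivity, specificity, and the predictive
  values carry exact Clopper–Pearson intervals (beta-quantile form).
  Likelihood ratios carry log-method intervals; when a zero (or full)
  cell makes the delta-method SE undefined, a 0.5 continuity correction
  is applied to the four cells *for the interval only*, with a warning.
  A perfectly specific test reports LR+ = ∞ with an open upper bound.
  Display rounding is round-half-up, one decimal for percentages and
  two for ratios.
* **Gray zone.** Two constructions: (1) the 2.5th–97.5th percentile
  band of the Youden cutoff over 1000 whole-cohort bootstrap replicates
  (non-stratified by default; single-class replicates are redrawn so
  exactly n_boot cutoffs enter; percentiles are outward nearest-rank,
  which is robust to replicates whose best cutoff sits at a sentinel);
  (2) a triadic zone whose lower bound is the largest cutoff keeping
  sensitivity ≥ 90% and whose upper bound is the smallest cutoff
  reaching specificity ≥ 90%, collapsing to the crossing midpoint when
  the bounds cross.  The wider zone is reported (ties favour the
  triadic construction), together with the cohort fractions below /
  inside / above the closed interval.
* **Trending.** Pearson r² with the t-based p-value; four-quadrant
  concordance of paired percent changes after excluding pairs with both
  |Δ| below a central exclusion zone (default 10%, the trending-analysis
  convention; the zone is configurable because published concordance
  rates rarely state it).  Paired and two-group comparisons route
  between t-tests (paired / Welch) and rank tests (signed-rank /
  Mann–Whitney) on a Shapiro–Wilk check at α = 0.05, and record which
  test ran.
* **Sample size.** Obuchowski's binormal-variance method:
  V(A) = 0.0099·e^(−a²/2)·[(5a² + 8) + (a² + 8)/R], a = √2·Φ⁻¹(A),
  which reduces to 0.0099·(8 + 8/R) at the null.  The default is
  one-sided (a directional alternative AUC > 0.5); the total is rounded
  half-up after multiplying the raw positive count by (1 + R).  At
  AUC 0.80 vs 0.50, R = 1.222, α = 5%, power 90% this yields 27
  patients, 32 after 15% dropout inflation — the planning numbers the
  package's acceptance script recomputes.

## The synthetic cohort generator

No patient-level data are deposited with the study the package
reproduces, so a generator supplies cohorts with the published group
structure: 32 patients, responder fraction 0.406, and group-wise
baseline and change summaries taken from the published tables
(responder ΔPI_LRM 55.23 ± 17.82%, non-responder 35.32 ± 17.32%, and
so on for all ten variables).

Key modelling choices, where the study reports only means ± SDs:

* **Marginals** are truncated normals with the underlying parameters
  solved numerically so the *truncated* mean and SD equal the printed
  targets exactly (naive truncation would bias heavily bounded
  quantities, e.g. the non-responder ΔPPV of 95.9 ± 102.5% on
  (−90, 600)%, by several points).  Bounds: baselines > 0, LRM
  decreases in (−50, 100)%, variation-index increases in (−90, 600)%,
  VE changes in (−90, 300)%.
* **Dependence.**  A Gaussian copula correlates the PI and SV LRM
  changes within group (latent ρ default 0.35, chosen so the pooled
  r² between ΔPI_LRM and ΔSV_LRM lands near the published 0.16 once
  the between-group mean separation is added).  The three arterial
  pressures share one latent factor per stage so DBP ≤ MAP ≤ SBP holds
  jointly; everything else is conditionally independent given group —
  real hemodynamics are certainly more entangled, but no further
  dependence is published.
* **Panels.**  T2 = T1 × (1 ∓ Δ_LRM/100); T3 = T1 × (published T3/T1
  ratio) × (1 + jitter), the jitter truncated so the <10%
  baseline-return rule always holds; T4 = T3 × (1 + Δ_VE/100) for the
  variables with a T3 measurement.  PPV/SVV/PVI have no T3 value (as
  in the published table) and draw T4 directly.
* **Labels.**  Δsv_VE is drawn per group so responders land at ≥ 10%
  with high probability (responder mean +22.07%, derived from the
  printed 59.8 → 73.0 mL; SDs 6 and 4 are modelling choices, not
  printed), and the stored label is re-derived from the realized value,
  so rare boundary crossings reassign it.  Calibration checks therefore
  compare against the *drawn* group, which `generate_cohort(...,
  return_draws=True)` exposes.
* **Unprinted summaries.**  The SVV LRM-change and all VE-change SDs
  are not published; means are derived from the published before/after
  group means (ratio of means) and SDs fixed once at physiologically
  plausible values (documented in `paper_default_spec`).

What passing tests show — and don't.  The generator reproduces the
published *group summaries* and the one published correlation; it does
not model beat-to-beat dynamics, measurement error of the esophageal
Doppler, within-patient coupling beyond the pressure triple and the
PI–SV pair, or any vasomotor-tone physiology.  Large-sample agreement
of the pipeline with binormal theory (AUC ≈ 0.79 at n = 10⁴) validates
the code, not the clinical result at n = 32.

## Numerical and degenerate-input conventions

* Changes are computed from full stored precision; rounding happens
  only in display.  CSV round-trips are bit-exact (`repr` formatting).
* Single-class label vectors raise a degenerate-input error everywhere;
  DeLong variance additionally requires two observations per class and
  otherwise raises (the pipeline catches this, reports a warning, and
  completes with the AUC point estimate).
* All-tied scores give AUC 0.5 and J = 0.
* One seeded generator per stochastic stage; a seed reproduces cohorts,
  bootstrap zones, and whole reports byte-identically.

## Problem sizes

Calibration and large-sample consistency checks run on one shared
10,000-patient cohort; bootstrap-coverage checks use 100 repetitions of
n = 500 with 1000 replicates; DeLong coverage uses 500 simulations at
the study's 13/19 group sizes.  These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the default
suite fast.

## Known limitations

* The gray-zone floors are applied to Sn/Sp (the stated construction);
  an alternative reading via predictive values is not implemented.
* The concordance rate depends on an exclusion zone and a pairing
  convention the source does not state; both are parameters rather than
  fixed guesses, so the printed 29.64% is not a target the package
  claims to reproduce.
* Sample-size planning covers one AUC against a null value only, not
  two correlated AUCs.
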