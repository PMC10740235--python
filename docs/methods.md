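# Methods

This note documents the statistical model behind `cuakit`, the choices
made where several defensible conventions exist, and what the synthetic
trials do and do not establish about real data.

## Design and estimands

The unit of analysis is the child or adolescent; randomisation is at the
family level, so siblings share both an arm and unobserved family-level
determinants of service use and quality of life. All estimands are
intention-to-treat arm contrasts Δ = INT − TAU in per-child annual
quantities:

* annual cost (€/year), averaged over 24 months and separately for each
  study year;
* QALYs (quality-adjusted life years per year) from a preference-based
  utility index.

Assessments occur at baseline (t0) and 6, 12 and 18 months (t1–t3). Each
assessment recalls the preceding 6 months, so t0 covers the pre-baseline
half-year. The 24-month annual average is therefore partly insensitive to
the intervention by construction — which is why the year-1 and year-2
measures are always computed alongside it.

## Costing

Service units are valued as `units × unit cost` per (category, item) and
summed within six categories per wave. The unit-cost table is a
user-supplied CSV; the placeholder table shipped with the package carries
plausible mid-2010s German magnitudes for testing only. With four wave
totals C_t0…C_t3:

    annual_total = (C_t0 + C_t1 + C_t2 + C_t3)/2,  annual_y1 = C_t0 + C_t1,  annual_y2 = C_t2 + C_t3

so `annual_total ≡ (annual_y1 + annual_y2)/2` is an exact algebraic
identity, enforced by tests on arbitrary panels. No discounting is applied
over the 24-month horizon and no price-year adjustment is attempted.

Intervention delivery is costed as staff time: hourly rate (default
€102.57, a blended psychiatrist/psychologist rate) × total session hours
per family (default 7 h) = €717.99/family, divided by the mean number of
children per family (1.6) → €448.74/child, optionally rounded to a
reporting granularity (€50 → €450). The default pipeline books the
rounded per-child cost to the intervention arm's first year only (and at
half weight into the 24-month average); both the rounding and the booking
are configurable because published analyses are rarely explicit about
either.

## Utilities and QALYs

Utilities come either directly (one score per wave) or via an additive
instrument-to-utility mapping `u = intercept + Σ coefficient(item, level)`
supplied as a CSV and clamped to declared bounds — the package ships no
valuation coefficients of its own, since published coefficient sets are
licensed work that must be supplied by the analyst. With two assessments
per year, each wave utility represents 0.5 QALYs and the annual measures
are plain means:

    QALY_total = (u_t0 + u_t1 + u_t2 + u_t3)/4,  QALY_year = mean of that year's two waves.

A trapezoid AUC alternative `(u0 + 2u1 + 2u2 + u3)/6` over the observed
18-month span is available but is not the default: the plain-mean
convention is what the 0.5-QALY-per-assessment reading implies, and it
keeps `QALY_total ≡ (QALY_y1 + QALY_y2)/2` exact.

## Missing data

Analysis requires an observed baseline: children missing t0 cost (any
category) or t0 utility are excluded, with per-arm counts reported.
Remaining gaps are imputed by last observation carried forward at the
finest level the tables support — per service category and per utility —
so category breakdowns stay internally consistent and partially assessed
waves retain their observed categories. LOCF never alters an observed
value and is idempotent (both are tested invariants). An explicit
`assessed` flag distinguishes a missing wave from a zero-use wave, because
retrospective inventories record non-use as zero. No multiple imputation
or mixed-model handling is offered; LOCF is the single-imputation method
this analysis chain is defined around.

## Inference

The mean model is `y = β0 + β1·1[INT] + ε`, so β̂1 is exactly the
difference in arm means. Uncertainty always treats the family as the
cluster:

* **CR1 sandwich**: V = c·(XᵀX)⁻¹(Σ_g s_g s_gᵀ)(XᵀX)⁻¹ with cluster
  scores s_g = X_gᵀe_g and c = G/(G−1). The plain G/(G−1) factor is used
  (≈200 families makes finer corrections immaterial); p-values use the
  normal reference by default, t with G−1 df optionally, α = 0.05.
* **Cluster bootstrap**: G families drawn with replacement (implemented
  as multinomial weights); every child of a drawn family enters as often
  as the family is drawn; the arm contrast is recomputed per replicate and
  the 2.5/97.5 percentiles reported. Replicates whose resample contains a
  single arm are discarded and logged (with ~200 families this is
  vanishingly rare). Percentile intervals, not BCa: nothing finer is
  claimed than a 95% interval.
* **Gamma GLM, log link**: the sensitivity model for right-skewed costs,
  fitted by statsmodels with cluster-robust covariance. Gamma support
  excludes zero, so when zeros are present a configurable offset (default
  €1) is added for this fit only. The arm effect is reported as a cost
  ratio with the model-implied €-difference alongside; it is used to
  confirm OLS significance conclusions, not to replace the OLS estimate.

Every stochastic routine takes an explicit seed (package default
20151201); fixed seeds give bit-identical outputs.

## Decision analysis

ICUR = ΔC/ΔE, flagged undefined (not thrown) when ΔE = 0, and always
reported on two scales — €/QALY and €/0.001 QALY — because published
ratios in this literature appear on both. Quadrants follow deterministic
tie rules: boundaries go to the positive-ΔE side, ΔC = 0 to the
cost-saving side. The bootstrap cloud resamples ΔC and ΔE jointly on the
same family resample, preserving their dependence. The CEAC is the
bootstrap fraction with λ·ΔE_b − ΔC_b strictly positive (net benefit
exactly zero counts as not cost-effective); a normal-theory variant
Φ(NMB/SE) is available. The NMB curve is affine in λ with slope ΔÊ and
intercept −ΔĈ; its variance at λ is λ²·Var(ΔÊ) − 2λ·Cov + Var(ΔĈ) from
the joint CR1 sandwich, with a cluster-bootstrap percentile band as the
alternative. The default λ grid is €0–125,000 in €1,000 steps.

## The synthetic generator

Defaults encode the study conditions the package is designed for: 105
families per arm, 1 or 2 children per family (mean 1.6), six cost
categories with 6-month means (€791.57, 206.06, 224.45, 131.10, 19.89,
518.18; total €1,891.25) and SDs far above the means, utilities
N(0.76, 0.07²) clipped to [0, 1], follow-up missingness with marginal
probabilities 96/327, 172/327, 170/327 at t1–t3 and ~3% baseline
incompleteness.

Costs follow a two-part model per category: a Bernoulli use indicator
(the zero mass implied by SD ≫ mean) times a lognormal positive part
whose (μ, σ) are solved from the target marginal mean and SD given the
use probability. Dependence is a Gaussian copula on the latent scale with
three levels — family (ICC 0.3), child persistence across waves (0.6 for
costs, 0.8 for utilities) and wave noise — because chronic service users
and stable quality-of-life trajectories are what make real annual sums so
dispersed. The family ICC is a design choice, not an estimate from any
dataset: trials of this kind do not publish one.

True effects are injected additively for the intervention arm: a per-wave
utility shift δ_E and a per-wave cost shift δ_C/2 on the outpatient
category (the annual measures sum two waves, so the annual contrast is
exactly δ_C). A *negative* cost effect is attenuated by the zero floor of
the outpatient category — the generator warns when it clips — so effect-
recovery experiments use non-negative cost shifts. Follow-up missingness
is independent across waves with the calibrated marginals (the calibrated
per-wave counts are themselves non-monotone, so a strictly monotone
dropout process cannot match them); an MNAR knob makes missingness depend
on baseline cost for robustness experiments. Ground truth — injected
effects and every planted missing set — is stored with each trial.

What the generator does *not* emulate: clinical symptom trajectories, the
intervention's mechanism, item-level response patterns of the utility
instrument (utilities are emitted directly; an item-level service mode
exists only to exercise the pricing path), cost–utility correlation
within children, and any MNAR structure beyond the single knob. Passing
tests therefore certify the analysis machinery under the assumed
structure, not the behaviour of any real dataset.

## Calibration results and numerical choices

Null-calibration runs (zero injected effects, no intervention-cost
booking — adding a known deterministic cost would make ΔC non-null by
construction) over 200 replicate trials show 95% percentile-CI coverage
of ≈0.93–0.96 for ΔC and ≈0.93–0.95 for ΔE at B = 500. The slight
undercoverage on the cost side is the known behaviour of percentile
bootstrap intervals for means of extremely skewed data at n ≈ 330; it is
reported, not corrected. On a matched-null trial (intervention arm an
exact clone of the control arm, making the arms exchangeable) the
B = 10,000 cloud spreads over the four CE-plane quadrants within ±0.03 of
0.25 each. An *ordinary* null trial does not have 0.25 shares: its cloud
centres on the trial's observed deltas, which sit O(1 SE) from the origin.

Costs are carried at full floating precision and rounded only in reports.
Simulation sizes in the test suite (200 null replicates at B = 500; 30
recovery replicates; one 2,000-family-per-arm trial for effect recovery)
are chosen so Monte-Carlo error is small against the tolerances tested
while the whole suite stays fast enough to run routinely.

## Known limitations

* LOCF is a strong assumption; under outcome-dependent dropout it biases
  toward baseline. The MNAR knob lets users measure this on synthetic
  data, but the package offers no correction.
* The gamma-GLM zero offset (default €1) is arbitrary at the margin;
  conclusions should not hinge on it, and the offset is configurable.
* Percentile bootstrap CIs undercover slightly for heavy-tailed costs at
  study-scale n (see above).
* Ratio inference for the ICUR is intentionally avoided beyond the cloud:
  when ΔE_b changes sign across replicates the ratio distribution is
  bimodal and percentile intervals for the ICUR itself are fragile; the
  CEAC and NMB curves are the stable summaries.
* Single comparator, no covariate adjustment, no value-of-information
  analysis, no discounting.
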