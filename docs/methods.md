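# Methods

## The model

Disease progression is modelled as an ordered sequence of *z-score events*.
Each biomarker `i` is a regional grey-matter volume expressed as a
sign-flipped z-score against controls (`x = -(v_adj - mu_c) / sigma_c`, so
larger x = more atrophy). An *event* `e_ir` is biomarker `i` reaching its
r-th threshold `z_ir`; the grid of thresholds defines `E = sum_i R_i`
events, hence `E + 1` stages (stage 0 = nothing has happened, stage E =
everything has). A subtype is a permutation `S` of all events respecting
within-biomarker threshold order, and the expected value of biomarker `i`
at stage `k` is the piecewise-linear interpolant `g_i(k)` through the
anchors `(0, 0)`, `(pos(e_ir), z_ir)` and `(E + 1, z_max_i)`. The z_max
anchor sits at the virtual stage `E + 1` so it can never collide with an
event at position E and `g` stays single-valued and non-decreasing.

Observations are Gaussian around the trajectory with per-biomarker SD
`sigma_i` (default 1, because inputs are control-referenced z-scores) and
stages carry a uniform prior:

    P(x | S, k)  = prod_i N(x_i; g_i(k), sigma_i)
    P(x | S)     = (1 / (E+1)) sum_k P(x | S, k)
    log L        = sum_j log sum_c f_c P(x_j | S_c)

for a mixture of `C` subtypes with fractions `f_c`. All likelihood work is
in log space; the stage sum uses log-sum-exp.

## Fitting

*Single sequence.* Greedy coordinate ascent from random valid permutations
(default 24 restarts): sweep events in random order, try every insertion
position that preserves within-biomarker threshold order, keep the argmax,
stop when a full sweep improves nothing. All candidate positions of a move
(including the current one) are scored by the same batched evaluator, so
keep-or-move comparisons are exact; ties break toward the lowest position
index, which makes the optimizer deterministic given its seed.

*Mixture.* Hierarchical: the C-subtype model is seeded from the (C-1)-model
by splitting one cluster. Candidate splits of a cluster's members are (a)
the worst-fitting quarter under the cluster's own sequence versus the rest
— subjects following an unmodelled ordering fit poorly, which makes this
split reliably find minority subtypes — and (b) random halvings. Each
candidate seeds fresh sequences on its two halves, then the whole mixture
is refined by EM: responsibilities `r_jc ∝ f_c P(x_j | S_c)` in the
E-step; fractions `f_c = mean_j r_jc` and responsibility-weighted greedy
re-ordering of every sequence in the M-step. Convergence at a log-likelihood
gain below 1e-6, capped at 100 iterations; an emptied cluster is reseeded
from the worst-fitting tenth of subjects with a logged warning. The best
refined candidate wins.

*Uncertainty.* Metropolis-Hastings over orderings with fractions held at
their maximum-likelihood values: per iteration pick one subtype and one
event uniformly, propose a uniformly random valid position (possibly the
current one, whose acceptance probability is then 1), accept with
min(1, L'/L) on the full-data likelihood. Every retained state contributes
to the positional-variance diagram M[e, p] (fraction of samples with event
e at position p; rows are probability vectors by construction).

*Number of subtypes.* Subject-level k-fold cross-validation (default 10)
with folds shared across candidate C (paired comparison);
`CVIC(C) = -2 x summed out-of-sample log-likelihood`. An extra subtype is
accepted if CVIC improves by more than a margin of 6 (strong evidence on
the deviance scale) or is within the margin while the mean per-fold test
log-likelihood strictly improves; otherwise the smaller model is kept.

*Default grid from data.* Candidate thresholds z = 1, 2, 3 are kept per
biomarker when they lie below the 95th percentile of patient baseline
z-scores (at least the first is always kept), and z_max is that percentile
floored at the last kept threshold. Regions with lower severity ceilings
thus get two events and severely atrophied ones three, reproducing the
mixed two-or-three-events-per-region pattern.

## Assignment and longitudinal validation

The posterior over (subtype, stage) is
`P(c, k | x) ∝ f_c P(x | S_c, k) / (E+1)`. The maximum-likelihood subtype
maximizes the stage-summed mass and the ML stage then maximizes within that
subtype (a two-step argmax; the joint argmax is available as an option but
conditioning matches the reported "most probable subtype" reading). The
expected stage averages k over every stage of every subtype. Scans whose
ML stage is 0 or E are flagged not subtypable: at those stages the subtype
trajectories coincide and a subtype label would be arbitrary.

Follow-up scans are z-scored with the baseline-fit adjuster and assigned
under the frozen baseline model. Consecutive visit pairs are classified as
consistent when both scans carry the same subtype, or when the earlier scan
was at stage 0 and the later one is subtypable; a pair that stays
non-subtypable is *not* consistent (it carries no evidence for the model).
Stage progression uses the ML stage (progressed / unchanged / regressed);
progression *rates* use the continuous expected stage, with pairs averaged
within subject before groups are compared by Welch t.

## Preprocessing

Left/right volumes with `_L`/`_R` suffixes are summed (an orphan hemisphere
is an error). Per-ROI OLS of volume on age, TIV, and treatment-coded sex,
field-strength and manufacturer indicators (reference = most frequent
control level) is fit on controls only and propagated to everyone:
`adjusted = observed - (predicted - mean control prediction)`, which keeps
adjusted volumes on the control-mean scale; a single-level categorical is
dropped with a warning and an unseen level maps to the reference with a
warning. Biomarker selection keeps ROIs with Cohen's d >= 0.6 (controls
minus patients, pooled-SD form, on covariate-adjusted baseline volumes).
Z-scoring uses the adjusted control mean and SD; follow-ups reuse the
baseline statistics (no refit). A scan missing any selected ROI is excluded
with a logged reason rather than imputed.

## The synthetic cohort generator

Real cohorts behind this kind of analysis are private, so the generator
emulates the study conditions end to end and carries its latent truth:

- 290 controls and 426 patients (configurable); covariates sampled to match
  the cohort demographics (controls ~62.5 +/- 9.4 y, patients 68.5 +/- 6.8 y;
  TIV 1.45e6 +/- 1.3e5 mm^3; 1.5 T/3 T mix; three manufacturers; three
  source cohorts).
- 24 regions with plausible mm^3 baselines; linear covariate effects on the
  raw volumes; paired regions written as left/right halves so the
  hemisphere-combining step is exercised.
- 20 regions carry disease signal over a 41-event true grid (midbrain
  crosses z = 1, 2, 3; the rest z = 1, 2; z_max 5/4/3 for
  midbrain/deep/cortical); 4 regions are spared so effect-size selection
  has something to reject. Volumes invert the z construction:
  `v = predicted_control - z x control_SD`.
- Two latent subtypes with fractions 0.75/0.25 built from region-wave
  cascades that share early brainstem events and diverge cortically.
  True stages are uniform over 0..E at baseline.
- Patient deviation from the trajectory has unit SD, decomposed into a
  persistent per-subject offset (95% of variance) plus scan noise.
  The split follows measurement physics: automated-segmentation test-retest
  error is about 1.5% of a region's volume against a between-subject spread
  of about 8%, i.e. scan noise is about 0.2 control SDs.
- Syndrome labels are drawn per subject from P(syndrome | subtype) anchored
  to the published subtype-by-syndrome table; with 0.75/0.25 fractions this
  reproduces the ~81/82/82% syndrome-to-subtype assignment pattern.
- Follow-ups: 0/1/2/3 visits with probabilities (0.31, 0.53, 0.155, 0.005),
  gaps Normal(0.91, 0.38) years re-drawn below a 0.25-year floor (imaging
  follow-ups are months apart, and rate = stage change / gap diverges as
  the gap shrinks). True stages advance by Poisson(rate x gap) — integer,
  non-negative, mean exactly rate x gap — with rates per syndrome:
  Richardson 1.86, subcortical variant 0.66, cortical variant 1.2
  stages/year (the cortical value is not published; 1.2 is a mid value).
  The subtype never changes; the stage caps at E.
- Clinical scores are `intercept + slope x stage + subtype offset + noise`,
  clipped to their published ranges, with signs matching the reported
  directions (motor-weighted scales worse in the subcortical subtype,
  everything worsening with stage, MMSE nearly flat).

What the generator does **not** emulate: spatial correlation of atrophy
beyond the event sequence, site-by-ROI interactions or scanner upgrades
mid-study, informative dropout (attrition independent of severity here),
floor/ceiling measurement artefacts beyond simple clipping, diagnostic
revision over time, and any true biological timescale. Passing recovery
tests therefore show the pipeline is correct and well-conditioned under the
stated noise model — not that the clinical findings would replicate on new
MRI data.

## Numerical choices

- Observation sigma = 1 per biomarker; configurable per grid.
- Uniform stage prior; fractions fixed during MCMC (only orderings are
  sampled); all samplers are `numpy.random.default_rng` seeded, and every
  pipeline is byte-reproducible under a fixed seed.
- Greedy move tolerance 1e-9 on the batched objective; EM tolerance 1e-6,
  cap 100 iterations; tie-breaks always toward the lower index.
- Degenerate inputs raise: non-increasing thresholds, z_max below the last
  threshold, missing biomarker values (no marginalization in this version),
  zero pooled variance, empty biomarker selection, constant logistic
  outcome, single-level ANOVA factors.

## Problem sizes in the test suite and acceptance script

Recovery experiments use the sizes the analysis itself is about where that
is cheap (n = 300-426 subjects, 10-20 biomarkers). The replicated
end-to-end studies (stage recovery, longitudinal consistency; 10 seeds) use
the full 24-region panel and grid with 200 controls / 300 patients and
reduced optimizer settings (2 greedy restarts, worst-fit split only, EM cap
10), which the recovery metrics are insensitive to; single full-size runs
use 3 restarts and EM cap 25. MCMC in examples and the acceptance script
runs 10^4 iterations rather than the 10^5 used for final positional
variance diagrams; the chains are seeded and the diagrams stabilize well
before 10^4 at these problem sizes.

## Known limitations

- No continuous-time variant: stages are ordinal, rates in stages/year
  depend on the fitted grid's resolution, so rates are comparable within a
  fitted model but not across grids with different E.
- No missing-biomarker assignment; scans missing a selected ROI are dropped.
- The hierarchical split plus EM is a local optimizer; the worst-fit split
  makes minority-subtype discovery reliable in the tested regimes, but
  global optimality is not guaranteed.
- Subtype labels are arbitrary (mixture label switching); downstream
  reports match labels to anatomy (or to truth, in simulations) explicitly.
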