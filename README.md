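# sustain-psp

Subtype-and-stage inference for spatiotemporal atrophy in progressive
supranuclear palsy (PSP), packaged as a reusable analysis pipeline with a
synthetic cohort generator.

PSP pathology produces a range of clinical syndromes (Richardson syndrome
and cortical/subcortical variants) whose relationship to the anatomical
spread of atrophy is hard to see in cross-sectional MRI. This package
implements the full analysis chain for uncovering that structure from
regional grey-matter volume tables: control-referenced covariate
adjustment, effect-size biomarker selection, a piecewise-linear z-score
subtype-and-stage mixture model fitted by greedy EM with hierarchical
splitting and MCMC ordering uncertainty, cross-validated selection of the
number of subtypes, per-scan subtyping and staging, longitudinal
consistency validation, and the post-hoc clinical statistics. It is aimed
at researchers who work with multi-site volumetric MRI cohorts of rare
neurodegenerative diseases and want a tested, seedable implementation of
this model class.

Because the MRI cohorts behind this kind of study are not public, the
package ships a first-class synthetic cohort generator whose defaults
emulate the study conditions (290 controls + 426 patients, 24 regions, two
latent subtypes at 75%/25%, syndrome-enriched labels, follow-up scans
0.91 ± 0.38 years apart progressing at syndrome-dependent rates), so every
stage of the pipeline is testable against known latent truth.

## The model

Each biomarker is a regional volume expressed as a sign-flipped z-score
against controls. An *event* is biomarker *i* reaching threshold *z*ᵢᵣ; a
subtype is an ordering *S* of all *E* events, and a subject at stage *k*
has passed the first *k* events. The expected biomarker value *g*ᵢ(*k*) is
piecewise linear through (0, 0), (pos(*e*ᵢᵣ), *z*ᵢᵣ) and (*E*+1, *z*ᵐᵃˣᵢ).
With Gaussian observation noise and a uniform stage prior, the data
likelihood of a C-subtype mixture with fractions *f*c is

    L = prod_j sum_c f_c · (1/(E+1)) · sum_k prod_i N(x_ji ; g_i(k|S_c), sigma_i)

Sequences are optimized by greedy coordinate ascent over orderings from
random restarts; subtypes are added hierarchically by splitting a cluster
and refining with EM; ordering uncertainty comes from Metropolis–Hastings
over permutations with fractions fixed; the number of subtypes is chosen by
a ten-fold cross-validation information criterion
(CVIC = −2 × out-of-sample log-likelihood). See `docs/methods.md` for the
full specification and numerical choices.

## Worked example

The `analysis/` scripts run the whole study in order. A reduced run
(200 controls, 300 patients, 3 greedy restarts) completes in a few minutes
on a laptop:

```
python analysis/01_simulate_cohort.py --seed 42 --n-controls 200 --n-patients 300
python analysis/02_preprocess.py
python analysis/04_fit_model.py --subtypes 2 --n-starts 3 --mcmc 2000
python analysis/05_assign_stage.py
python analysis/06_longitudinal_validation.py
python analysis/07_clinical_stats.py
```

which prints (numbers from this exact invocation):

```
wrote results/cohort.csv: 200 controls, 300 patients, 273 follow-up scans
wrote results/truth.csv: 2 latent subtypes, stage range 0-41
selected 20/24 regions at d >= 0.6 (strongest: roi_ventral_dc d = 1.99)
residual age association in controls: 0/24 regions with |t| >= 2 (median |t| = 0.00)
residual age association in patients: 4/24 regions with |t| >= 2 (median |t| = 0.88)
wrote results/zscores.csv (773 scans x 20 biomarkers)
fitting 2 subtype(s) on 300 patients, E = 56 stages
mixture fractions: [0.73 0.27], log-likelihood -9289.8
  subtype 0 first events: putamen:z1, ventral_dc:z1, pons:z1, pallidum:z1, dentate:z1 ...
  subtype 1 first events: cingulate:z1, thalamus:z1, ventral_dc:z1, midbrain:z1, frontal_posterior:z1 ...
MCMC acceptance rate 0.371 over 2000 iterations
assigned 773 scans (573 patient scans); 12 patient scans not subtypable (2.1%)
subtypable patient scans by subtype: {0: '74.2%', 1: '25.8%'}
subtype stability: 92.7% (253/273 visit pairs consistent)
stage progression: 66.7% later, 21.2% same (same-or-later 87.9%)
              mean    std  count
group
RS           2.024  2.364    183
cortical     2.374  2.818     19
subcortical  1.097  1.386     16
RS vs subcortical rate difference 0.93 stages/year (t = 2.39, p = 0.025, 95% CI 0.13 to 1.73)
292/300 baseline patients subtypable
syndrome x subtype: chi2(2, N = 292) = 19.1, p = 7.29e-05
  77% of RS cases in subtype 0
  59% of cortical cases in subtype 1
  89% of subcortical cases in subtype 0
PSPRS by subtype: 36.2 vs 33.3 (t = 1.7)
10/10 scores associated with stage at the corrected level
subtype ~ covariates: stage term z = 0.68, p = 0.50 (no dependency expected)
mean stage by syndrome: {'RS': 24.1, 'cortical': 27.2, 'subcortical': 15.1}
```

Reading the output: 20 of the 24 regions pass the Cohen's d ≥ 0.6 screen
(the four spared regions are rejected); the two-subtype fit recovers a
73/27 split against the generating 75/25 mixture; covariate adjustment
leaves no residual age association in controls; at follow-up 93% of
patients keep their subtype and 88% move to the same or a later stage; and
Richardson-syndrome cases progress about twice as fast as
subcortical-variant cases (whose mean fitted stage, 15.1, is also well
below the Richardson 24.1). Syndrome enrichment in the minority subtype is
attenuated at this reduced size — full-size runs (426 patients, as in
`scripts/acceptance.py`) recover it more sharply. `03_select_subtypes.py`
runs the cross-validated comparison of one- versus two-subtype models
(slower; CVIC strongly prefers two on this cohort).

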