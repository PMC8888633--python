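# Methods

## Signal model and ADC estimation

All computation assumes the mono-exponential diffusion decay
`S(b) = S(0)·exp(−b·A)` per voxel, with A the apparent diffusion
coefficient (mm²/s).  The estimator is the ordinary least-squares slope
of log-signal against b over the **native** acquisitions only; no
weighting by b or SNR is applied, and multi-compartment models (IVIM,
kurtosis) are deliberately out of scope.  On noiseless
mono-exponential input the estimator is exact to machine precision for
any positive decay rate and any ≥ 2 distinct b-values, and it is
invariant to global signal scaling; both properties are enforced by
tests.

Signals are clamped to a floor before the log transform.  The floor
defaults to 1e-6 × the maximum over the *native* volumes: small enough
that it never touches genuine tissue signal, large enough to keep the
log finite at air voxels.  The native restriction matters — at voxels
where noise drives the fitted slope negative, the synthetic b = 7000
volume can reach arbitrarily large values, and a floor derived from the
extended series would scale with those excursions and clamp real
signal.  Voxels where clamping occurred are recorded in the ADC map's
`fit_mask`.  Negative fitted ADCs are retained by default (the raw
estimator is the faithful one); `clamp_adc_nonnegative` floors them at
zero for users who prefer monotone extrapolation everywhere.

Synthetic acquisitions extrapolate from the b = 50 s/mm² native
reference — the highest-SNR image — to 1000…7000 s/mm² in 1000 steps.
Appending synthetic volumes never changes a subsequent ADC fit, since
fitting reads native entries only.

## The mixing operator

The correlated-diffusion map is the contribution-weighted product of
the signals over the b-value set {50, 1000, …, 7000}, spatially
averaged and calibrated:

* **Product.** Π_k S_{b_k}(x′)^{ρ_k}, evaluated as
  exp(Σ ρ_k log S_k) — eight factors spanning many orders of magnitude
  make log-space evaluation the numerically stable choice.
* **Spatial weighting.** The local expectation is read
  deterministically as a Gaussian kernel average: weights proportional
  to the Gaussian density with diagonal covariance Σ = (4, 4, 0) mm² at
  voxel-center offsets, truncated to the 6 × 6 × 3 mm local volume V
  and renormalized to sum 1.  A zero variance entry is treated as a
  delta: the stencil spans only the central slice, so V's 3 mm
  through-plane extent equals one slice at the 3 mm default thickness.
  On the default 2 × 2 × 3 mm grid this yields a 3 × 3 × 1 stencil.
* **Boundaries.** Neighborhoods are clipped at the volume edge and the
  remaining weights renormalized, so edge voxels stay averages of real
  data rather than mixing with padding.
* **Calibration.** Z is the median of the unnormalized map within the
  whole 3-D gland mask, computed once per case.  The calibrated map is
  dimensionless with gland median exactly 1.  Because scaling by Z is
  rank-preserving, single-case ROC analysis is unaffected by
  calibration; cross-case pooling is affected, which is exactly its
  purpose (dynamic-range consistency across scanners/protocols).

The fast implementation convolves the product map with the stencil
(scipy) and is verified against a brute-force triple loop
(voxel × neighborhood × b) to 1e-9 on random grids.

A `log(1 + C)` transform is provided for display only — the map is a
product of exponentials, so contrast reads more naturally in log space —
and never feeds statistics.

## Coefficient tuning

The tuned variant maximizes voxel-pooled delineation AUC over ρ with
Nelder–Mead, started at ρ = 1 with per-vertex perturbation 0.25,
tolerances 1e-4 on objective and parameters, and at most 500·d
evaluations.  In log space the score is linear in ρ, so scaling ρ by a
positive constant leaves all voxel ranks — and the AUC — unchanged.
That exact ridge is hostile to a simplex search, so the first
coefficient is frozen at 1 by default (only relative exponents matter);
the option can be disabled, and a test confirms the optimizer still
never returns worse than baseline without it.  The result reported is
the best *evaluated* vertex, which together with the guaranteed
evaluation of the start point makes `auc_opt ≥ auc_baseline` structural.
Per-case median-gland calibration is applied inside the objective
because pooling across cases depends on per-case scale.  The search has
no randomness; reruns are bit-identical.

## Delineation statistics

Voxels inside the gland are pooled over cases for four tasks
(csPCa-vs-healthy, csPCa-vs-insPCa, csPCa-vs-rest, PCa-vs-healthy);
healthy is gland minus all lesions by construction.  ROC curves are
empirical with tied scores grouped at one threshold; AUC is the
trapezoidal area, equal to Mann–Whitney concordance with half-credit
ties (cross-checked against an all-pairs oracle).  Scores are oriented
per modality before pooling — correlated-diffusion maps and K^trans
positively, ADC and T2w negatively (cancer is hypointense on those).

AUC differences between modalities computed on the same cases are
tested with the Hanley–McNeil critical ratio; the standard error uses
the exponential-model closed form with Q₁ = A/(2−A), Q₂ = 2A²/(1+A)
and pooled voxel counts n_P, n_N (the counts are reported so
alternative granularities can be recomputed).  The correlation r
between the two AUC estimates is interpolated bilinearly at
(mean Pearson r, mean AUC) from a packaged lookup table.  Because the
native resolutions of the modalities differ, the Pearson correlations
are computed not voxel-to-voxel but across per-case class medians
(positives and negatives separately), using score-oriented maps so the
correlations refer to the same direction as the ROC analysis.

The table itself (`data/hanley_mcneil_r_table_synthetic.tsv`) is
generated by `scripts/make_hm_table.py` from the binormal large-sample
model of two correlated Mann–Whitney estimators,
`r = (L(r_avg/2) − A²)/(L(1/2) − A²)` with L the bivariate-normal
orthant probability — a synthetic, model-derived table rather than a
transcription, with the correct boundary behavior (r = 0 at r_avg = 0,
r = 1 at r_avg = 1).  Inputs beyond the grid clamp to the boundary; a
mean AUC below 0.5 is folded to 1 − A.  p-values are two-sided normal
with no multiple-testing correction.

## The phantom generator

Each case is an ellipsoidal gland partitioned into a transition-zone
ellipsoid, an anterior stromal slab, and a peripheral-zone remainder,
with spherical lesions labelled csPCa or insPCa.  Tissue classes carry
(S0, ADC) pairs realizing the restricted-diffusion picture:

| tissue      | S0 (a.u.) | ADC (10⁻³ mm²/s) | rationale |
|-------------|-----------|------------------|-----------|
| healthy PZ  | 1000      | 1.8              | glandular, fast decay |
| TZ          | 750       | 1.3              | mixed stromal/glandular |
| AS          | 420       | 0.8              | stroma: low signal at every b, ADC in the cancer range |
| insPCa      | 1000      | 1.0              | mildly restricted |
| csPCa       | 1250      | 0.7              | dense cellularity: high signal across all b |

The anterior-stroma row encodes the known failure mode of ADC maps —
benign stroma sharing the cancer ADC range — while its low baseline
signal keeps its correlated-diffusion product low.  This is the tissue
contrast mechanism the method targets, and it is what makes the
end-to-end ordering AUC(CDI^s) ≥ AUC(ADC) on the default cohort a
statement about the mechanism, not about any particular dataset.

Noise is Rician (modulus of signal plus circular complex Gaussian),
the standard model for magnitude MRI, with default scale σ = 25 —
SNR ≈ 40 at b = 50 in healthy PZ, mid-range for clinical prostate DWI.
The default grid is 96 × 96 × 12 voxels at 2 × 2 × 3 mm.  Cohorts
(`default_study_spec`) jitter geometry and tissue parameters ±8–10% per
case, place 1–3 lesions of radius 4–8 mm per case, and draw lesion
classes csPCa with probability 76/299 ≈ 25.4%, the tumor-level class
mix of the emulated clinical cohort.  A noiseless T2w-like anatomical
volume (scaled by a per-case receiver-gain factor so cohort-level
statistics have variance) is emitted for overlay and comparison
testing.  Everything derives from a single integer seed;
`numpy.random.default_rng` sub-seeds give per-case determinism.

What the phantom does *not* emulate: k-space artifacts, eddy-current
distortion, B1 inhomogeneity, partial-volume mixtures, lesion
heterogeneity, or inter-sequence misregistration.  Passing tests on
phantoms therefore demonstrate correctness of the computation and the
qualitative tissue-contrast mechanism — not clinical performance
levels, which depend on real-tissue variability the phantom cannot
supply.

## Numerical and design choices

* Common grid: everything is resampled to the grid of the lowest-b
  native DWI volume (linear for signals, nearest-neighbour for masks);
  the nonlinear signal model is never interpolated after computation.
  Only rigid header-based resampling is supported.
* World coordinates follow the DICOM patient convention (LPS); NIfTI
  affines are converted and volumes reoriented to canonical axes on
  load, preserving voxel world positions to 1e-6 mm.
* NaN voxels in input volumes are mapped to 0 with a logged warning;
  orientation matrices must be orthonormal to 1e-6.
* Lesion masks must keep ≥ 95% of their voxels inside the gland after
  resampling (tolerating nearest-neighbour edge effects); total
  disjointness is an error.
* Study sizes: the shipped analyses use a 20-case default cohort
  (~2 600 gland voxels per case, ~54 000 pooled voxels per task),
  which gives stable pooled AUCs while keeping any analysis
  reproducible in well under a minute.

## Known limitations

* The Hanley–McNeil r table is model-derived (binormal, large-sample);
  published tabulations were simulation-based and may differ in the
  second decimal in places.  The interpolation machinery is agnostic to
  the table file, which can be regenerated or replaced.
* n_P and n_N in the SE formula are pooled voxel counts; voxels within
  a patient are spatially correlated, so the reported SEs (and z
  magnitudes) are optimistic in the same way the source framework is
  when applied at voxel granularity.
* K^trans is ingested only as a precomputed map; no pharmacokinetic
  fitting is performed.
* Tuning optimizes on the supplied cohort without a train/test split;
  the tuned AUC is an in-sample quantity.
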