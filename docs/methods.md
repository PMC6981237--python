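# Methods

This note records the statistical model behind `ionratio`, the package's own
parameter choices, and the design of the synthetic data generator used for
validation, including its known limits.

## 1. Problem setting

Untargeted LC-MS fingerprinting of a sample cohort yields, per injection, a
multi-scan profile spectrum. The goal is a *minimal discriminant
fingerprint*: a handful of ion-intensity ratios whose values separate sample
classes (e.g. product origin) with a linear classifier. Ratios rather than
raw intensities are used because a per-injection global intensity factor
(source efficiency, injected amount) multiplies every ion of a spectrum
equally and cancels exactly in any intensity quotient; the representation is
normalization-free by construction.

## 2. Preprocessing

**Scan summation.** The intensities of a fixed scan window (default scans
240–295, the elution region of interest) are summed point-wise on the shared
m/z grid, collapsing the injection to one high-signal spectrum.

**Baseline subtraction.** The m/z range is divided into 200 equal intervals;
each interval's minimum anchors the baseline, the anchors are smoothed with
lowess (`frac = baseline_bandwidth`, default 0.1, 2 robustness iterations),
and the smoothed curve is interpolated back to the grid and subtracted,
flooring at zero. Anchoring on interval minima rather than regressing the
raw signal keeps narrow peaks out of the baseline: peak apex heights are
preserved to within 5% in the test suite.

**Peak detection.** The signal is smoothed with a centred moving average
(span 5). Local maxima of the smoothed signal are candidates (plateaus keep
their lowest-m/z point). A candidate at smoothed height `h` is a peak when

1. `h > zerothrsh` (absolute floor, default 2·10⁴ counts),
2. `h > son ×` noise, where noise is 1.4826 × MAD of (raw − smoothed) in a
   ±0.05-range window around the candidate (the candidate's own ±2 points
   excluded), default `son = 1.5`,
3. `h > 1.64 ×` MAD of the smoothed signal in the same window.

Rules 2–3 are scale-invariant; only rule 1 depends on the intensity unit.

## 3. Alignment

Peaks from all injections are pooled and clustered on absolute m/z
difference with complete linkage, so a cut at height `c` bounds every
cluster's m/z spread by `c`. The pooled, sorted peak list is split into
segments wherever consecutive peaks are more than the largest candidate
cutoff apart; exact linkage within each segment reproduces the full result
at any smaller cutoff (complete linkage cannot merge across such a gap).

The cutoff is chosen from a logarithmic grid (0.001–0.5 Th, 20 points) to
minimize the number of clusters that contain two peaks from the *same*
injection — the signature of over-merging; ties go to the larger cutoff
(fewer split features). Each cluster becomes one consensus feature (mean
member m/z); a spectrum's feature intensity is its member peak height
(summed if several of its peaks fall in one cluster). Technical replicates
are then averaged arithmetically into one row per biological sample.

## 4. Annotation

Features are matched against an in-house compound list by signed relative
mass error, `ppm = (theoretical − experimental) / theoretical × 10⁶`, within
a tolerance (default 10 ppm). All matches are reported; multi-match features
are flagged ambiguous. Downstream ratio building can be restricted to
annotated features.

## 5. Ratio features and search space

For `p` retained features, all ordered quotients are formed: `p(p−1)`
ratios (both orientations kept — LDA on raw ratios is not symmetric under
inversion). Zero intensities are first imputed with half the smallest
positive value of their column. 72 annotated features give 5112 ratios;
fingerprints of 1–10 ratios span Σₖ C(5112, k) ≈ 3.3·10³⁰ subsets, which
motivates a heuristic search.

## 6. Discriminant and cross-validation

The classifier is the Gaussian equal-covariance discriminant (LDA): class
means, pooled within-class covariance with a relative ridge
(`1e-8 · trace/d` on the diagonal), empirical priors, deterministic
tie-break toward the earlier class label. Accuracy is estimated by repeated
stratified 2-fold cross-validation: per repeat, each class is shuffled and
dealt into two folds, so no fold loses a class.

## 7. GA subset selection

Individuals are variable-length ratio-index sets (sizes 1–10). Fitness is
the stratified 2-fold CV accuracy of an LDA on the subset's columns (splits
fixed per run, so cached fitness values are exact). Evolution: tournament
selection (size 3), elitism (2), a pooling crossover that redraws children
from the union of the parents, and a replace/add/drop mutation. Several
independent runs are pooled and every distinct final-generation individual
is ranked by:

1. 30-repeat 2-fold CV accuracy on the learning set (one shared split set);
2. survivors must exceed an accuracy floor (0.80);
3. survivors' LDA models, refit on the whole learning set, are scored on an
   independent validation set;
4. maximize validation accuracy; ties break toward fewest distinct
   molecules, then fewest ratios, then highest CV accuracy.

If nothing clears the floor the best-by-CV solution is returned with a
warning.

**Hyperparameters are this package's own choices** (the published analysis
does not state its GA settings). Library defaults: population 100, 200
generations, 5 runs, crossover 0.8, mutation 0.2. For the validation studies
(planted-pair recovery, oracle comparison) we instead use many short,
high-mutation runs — recovery: population 150 × 40 generations × 10 runs,
mutation 0.3; oracle: population 150 × 25 generations × 12 runs, mutation
0.5, sizes restricted to the enumerated 1–2. Rationale: the in-loop fitness
saturates at 1.0 within a few generations on separable cohorts, after which
longer runs only let populations converge onto arbitrary saturated subsets;
the ranking stage then needs *diversity* across runs, because its deciding
statistic (validation accuracy) is never seen by the GA. These settings were
fixed from small pilot sweeps before the corresponding tests were frozen.

## 8. Random-forest benchmark

A random forest on all ratios, tuned by out-of-bag accuracy over
`n_trees ∈ {250, 500, 1000}` × per-split candidates `{√p, p/10, p/3}`
(ties toward the smaller model). Ratios are ranked by out-of-bag permutation
importance (per tree: OOB accuracy drop after permuting one column, one
shared permutation per column), and reduced forests are refit on the top-k
ratios. Each model is reported with learning, repeated-2-fold-CV, and
validation accuracy. On small cohorts the forest memorizes the learning set
(learning accuracy 1.0) while validation accuracy lags — the overfit gap the
benchmark is meant to expose.

## 9. Synthetic data generator

`simulate_cohort` draws, for `K` classes × `n` samples × `r` replicates over
`p` peaks:

```
X[sample, peak] = base[peak] · shift[class, peak] · bio[sample, peak]
                  · inj[injection] · tech[injection, peak]
```

* `base`: log-uniform over the configured intensity range (default
  10⁵–10⁶).
* `shift`: for each planted pair (i, j) with centred class scores `s_c`
  (adjacent classes one unit apart), peak i is scaled by
  `effect^(+s_c/2)` and peak j by `effect^(−s_c/2)`, so the planted *ratio*
  moves by exactly `ratio_effect_size` per class step while each single peak
  carries only half the log-effect. Each planted pair uses a rotated class
  score pattern so peaks from different pairs never combine into an equally
  strong cross-ratio.
* `bio`: per-sample log-normal biological variation (mean 1, cv
  `intensity_noise_cv` = 0.15), shared by a sample's technical replicates.
  The two peaks of a planted pair additionally share a per-sample
  covariation factor (log-sd `pair_covariation_sd` = 0.5) that cancels in
  their ratio — modelling co-regulated compounds — so neither planted peak
  is informative alone and "partial" ratios (planted/background) are noisy.
* `inj`: per-injection global log-normal scale (log-sd 0.5); cancels in
  every ratio.
* `tech`: per-injection, per-peak log-normal technical noise (cv 0.05),
  attenuated by replicate averaging.

Separating biological from technical variance matters: if all peak noise
were technical, triplicate averaging would remove nearly all of it and every
half-effect ratio would saturate the classifier, making recovery of the
specific planted pair meaningless.

**Realism and limits.** The generator reproduces the properties the method
relies on (injection-factor invariance of ratios, replicate structure,
planted multiplicative class effects, log-normal abundance noise) but not
full LC-MS physics: no isotope patterns, adducts, in-source fragments,
retention-time structure, detector saturation, or heteroscedastic shot
noise; peak shapes in rendered spectra are ideal Gaussians with small m/z
jitter. Conclusions from it validate the *workflow machinery*, not
instrument-specific performance.

`simulate_spectrum` renders multi-scan profile spectra (Gaussian peaks,
linear baseline, i.i.d. noise, clipped at zero) for exercising
preprocessing; `cohort_to_spectra` renders each cohort row so the full
pipeline (detection → alignment → averaging) can be tested end to end.

## 10. Numerical choices

* LDA ridge `1e-8 · trace/d`: negligible at fingerprint scale (2–10
  features), prevents singular pooled covariances on degenerate folds.
* Complete-linkage clustering runs exactly on gap-delimited segments; no
  approximation is introduced.
* Big-integer subset counts use exact integer arithmetic (`math.comb`).
* All stochastic components take explicit seeds; every pipeline artifact
  records the master seed, and reruns are byte-identical.
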