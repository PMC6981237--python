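# ionratio

Ion-intensity-ratio fingerprinting for mass-spectrometry sample
discrimination: from raw multi-scan LC-MS spectra to a minimal panel of
intensity ratios that separates sample classes with a linear classifier.

## The scientific problem

Untargeted ("shotgun") LC-MS fingerprinting measures hundreds of ion
intensities per sample, but absolute intensities are unreliable: the
injected amount and source efficiency multiply every ion of an injection by
an unknown global factor. The quotient of two ion intensities from the same
spectrum cancels that factor exactly, so **ratios are a normalization-free
representation**. The question is which few ratios — out of `p(p−1)` ordered
quotients of `p` aligned peaks (5112 for 72 peaks), and ~3.3·10³⁰ candidate
panels of 1–10 of them — form a small, chemically interpretable fingerprint
that classifies new samples correctly.

`ionratio` implements the complete workflow:

1. **Preprocessing** — scan-window summation, minimum-anchored lowess
   baseline subtraction, moving-average peak detection with absolute and
   signal-to-noise thresholds.
2. **Alignment** — complete-linkage clustering of pooled peak m/z values;
   the cut height is chosen to minimize co-clustering of distinct ions from
   the same spectrum; technical replicates are averaged.
3. **Annotation** — exact-mass matching against a compound list within a
   signed ppm tolerance, `(theoretical − experimental)/theoretical × 10⁶`.
4. **Ratio features** — all ordered pairwise quotients, zeros imputed with
   half the column minimum.
5. **GA selection** — a genetic algorithm over variable-size ratio subsets
   with 2-fold cross-validated LDA accuracy as fitness, followed by a
   multi-stage ranking (30-repeat CV, 0.80 accuracy floor, independent
   validation, ties toward the smallest panel).
6. **Random-forest benchmark** — OOB-tuned forest on all ratios with
   out-of-bag permutation importance and importance-reduced refits, exposing
   the training/validation overfit gap that motivates the small LDA panel.
7. **Synthetic cohorts** — a generator that plants known discriminant ratio
   pairs inside realistic injection/biological/technical noise, so recovery
   can be asserted against ground truth.

See `docs/methods.md` for the full model and parameter rationale.

## Worked example

A synthetic cohort at the study design scale: 3 classes × 20 samples, 72
aligned peaks, 2 planted ratio pairs whose class means step by a factor 3,
log-normal biological (cv 0.15), injection (log-sd 0.5) and technical
(cv 0.05) noise:

```python
import numpy as np
import ionratio as ir

cfg = ir.CohortSimConfig(n_peaks=72, n_samples_per_class=20,
                         n_discriminant_ratio_pairs=2,
                         ratio_effect_size=3.0, seed=1)
matrix, truth = ir.simulate_cohort(cfg)
print([(p.numerator, p.denominator) for p in truth])
# [(19, 35), (63, 56)]

learn, valid = ir.split_learning_validation(matrix, 10, seed=11)
rl, rv = ir.build_ratios(learn), ir.build_ratios(valid)
print(rl.n_ratios)            # 5112 ordered ratios
y, yv = np.asarray(rl.class_labels), np.asarray(rv.class_labels)

ga = ir.GAConfig(population_size=150, n_generations=40,
                 n_ga_runs=10, mutation_prob=0.3, seed=2)
finals = ir.run_ga(rl, y, ga)
sol = ir.rank_and_select(finals, (rl.ratio_matrix, y), (rv.ratio_matrix, yv),
                         pairs=rl.pairs, pair_labels=rl.pair_labels, seed=3)
print(sol.pair_labels, sol.ratio_pairs, sol.n_molecules)
# ['332.2657/485.4446'] [(19, 35)] 2
```

Out of 5112 candidate ratios the search returns a **single planted ratio**
(two molecules). Its three-way evaluation:

```python
learn_acc, cv30, val_acc = ir.evaluate_solution(
    sol.ratio_indices, (rl.ratio_matrix, y), (rv.ratio_matrix, yv), seed=3)
print(f"learning={learn_acc:.3f} cv30={cv30:.3f} validation={val_acc:.3f}")
# learning=1.000 cv30=0.980 validation=1.000
```

The random-forest benchmark on *all* 5112 ratios memorizes the learning set
but transfers far worse — the overfit gap the small panel avoids:

```python
from ionratio.rf import RFGrid, rf_full
rep = rf_full(rl, y, grid=RFGrid(n_trees=(250,), mtry_rules=("sqrt",)),
              valid=(rv, yv), n_cv_repeats=2, seed=4,
              compute_importance=False)
print(f"learning={rep.learning_accuracy:.3f} "
      f"cv={rep.cv2_accuracy:.3f} validation={rep.validation_accuracy:.3f}")
# learning=1.000 cv=0.800 validation=0.833
```

## Command line

Each stage is a subcommand (`simulate`, `preprocess`, `align`, `annotate`,
`ratios`, `select`, `rf-benchmark`), plus `run-all` for the whole chain:

```bash
ionratio config show                      # print all defaults as YAML
ionratio run-all --config study.yaml --set ga.population_size=150
```

`run-all` writes every intermediate artifact (aligned matrix, annotations,
solution JSON, accuracy table, manifest with seed and versions) to the
configured output directory; reruns with the same config are byte-identical.
Spectra are read from mzML or a plain two-column text dialect; matrices and
compound lists travel as CSV.

## Reproduction

All randomness is seed-controlled. To reproduce the validation summary:

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -q tests/                       # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports, under the given seed: the search-space
counts, the reference ppm errors, GA+LDA and random-forest accuracies on a
design-scale synthetic cohort, the planted-pair recovery rate over 20
worlds, permutation-null accuracies, and the fraction of worlds with a
non-negative random-forest overfit gap.
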