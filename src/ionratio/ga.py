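"""Genetic-algorithm search over ratio subsets with CV-LDA fitness.

Individuals are variable-length sets of ratio-column indices (size 1-10 by
default). Fitness is the stratified 2-fold cross-validated LDA accuracy on
the subset's ratio columns. Evolution uses tournament selection with
elitism, a pooling crossover that preserves the size bounds, and a
replace/add/drop mutation. Several independent runs are performed; all
final-generation individuals are then ranked by a multi-stage procedure:
30-repeat 2-fold CV on the learning set, an accuracy floor, validation-set
scoring of the survivors, and tie-breaking toward the smallest fingerprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .discriminant import (
    _cv_accuracy,
    accuracy,
    fit_lda,
    predict,
    stratified_splits,
)
from .features import RatioFeatureSet

__all__ = [
    "GAConfig",
    "GASolution",
    "run_ga",
    "rank_and_select",
    "evaluate_solution",
]


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    The published analysis's exact settings are not available, so these
    defaults are the package's own; every field is overridable from the CLI
    config. ``fitness_cv_repeats`` controls how many repeats of the 2-fold CV
    the in-loop fitness uses (1 by default; the final ranking always uses
    ``rank_cv_repeats``).
    """

    population_size: int = 100
    n_generations: int = 200
    subset_size_range: tuple[int, int] = (1, 10)
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    n_ga_runs: int = 5
    elitism: int = 2
    tournament_size: int = 3
    fitness_cv_folds: int = 2
    fitness_cv_repeats: int = 1
    rank_cv_repeats: int = 30
    accuracy_floor: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        kmin, kmax = self.subset_size_range
        if not 1 <= kmin <= kmax:
            raise ValueError("subset_size_range must satisfy 1 <= min <= max")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population_size < 2 or self.elitism >= self.population_size:
            raise ValueError("population_size must exceed elitism and be >= 2")
        if self.n_generations < 1 or self.n_ga_runs < 1:
            raise ValueError("n_generations and n_ga_runs must be >= 1")


@dataclass
class GASolution:
    """A selected ratio fingerprint with its evaluation record."""

    ratio_indices: tuple[int, ...]
    ratio_pairs: list[tuple[int, int]]
    fitness: float
    learning_accuracy: float | None = None
    cv30_accuracy: float | None = None
    validation_accuracy: float | None = None
    n_molecules: int = 0
    pair_labels: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ratio_indices": list(self.ratio_indices),
            "ratio_pairs": [list(p) for p in self.ratio_pairs],
            "pair_labels": self.pair_labels,
            "fitness": self.fitness,
            "learning_accuracy": self.learning_accuracy,
            "cv30_accuracy": self.cv30_accuracy,
            "validation_accuracy": self.validation_accuracy,
            "n_molecules": self.n_molecules,
        }


def _ratio_matrix(ratios) -> np.ndarray:
    return ratios.ratio_matrix if isinstance(ratios, RatioFeatureSet) else np.asarray(ratios, float)


class _Fitness:
    """CV-LDA fitness with caching keyed by the sorted ratio subset."""

    def __init__(self, X: np.ndarray, y, k: int, n_repeats: int, seed: int):
        self.X = X
        y = np.asarray(y)
        _, self.y_codes = np.unique(y, return_inverse=True)
        self.n_classes = int(self.y_codes.max()) + 1
        self.splits = stratified_splits(y, k, n_repeats, seed)
        self.cache: dict[tuple[int, ...], float] = {}

    def __call__(self, subset: tuple[int, ...]) -> float:
        val = self.cache.get(subset)
        if val is None:
            val = float(
                _cv_accuracy(
                    self.X[:, list(subset)], self.y_codes, self.n_classes, self.splits
                ).mean()
            )
            self.cache[subset] = val
        return val


def _random_subset(rng, n_ratios: int, kmin: int, kmax: int) -> tuple[int, ...]:
    size = int(rng.integers(kmin, min(kmax, n_ratios) + 1))
    return tuple(sorted(rng.choice(n_ratios, size=size, replace=False).tolist()))


def _crossover(rng, a, b, kmin, kmax) -> tuple[tuple[int, ...], tuple[int, ...]]:
    pool = sorted(set(a) | set(b))
    lo, hi = sorted((len(a), len(b)))
    children = []
    for _ in range(2):
        size = int(rng.integers(lo, hi + 1))
        size = max(kmin, min(size, len(pool), kmax))
        children.append(tuple(sorted(rng.choice(pool, size=size, replace=False).tolist())))
    return children[0], children[1]


def _mutate(rng, subset, n_ratios, kmin, kmax) -> tuple[int, ...]:
    s = set(subset)
    ops = ["replace"]
    if len(s) < min(kmax, n_ratios):
        ops.append("add")
    if len(s) > kmin:
        ops.append("drop")
    op = ops[int(rng.integers(len(ops)))]
    if op == "drop":
        s.remove(subset[int(rng.integers(len(subset)))])
    else:
        if op == "replace":
            s.remove(subset[int(rng.integers(len(subset)))])
        while True:
            cand = int(rng.integers(n_ratios))
            if cand not in s:
                s.add(cand)
                break
    return tuple(sorted(s))


def _tournament(rng, population, fitnesses, size) -> tuple[int, ...]:
    idx = rng.integers(len(population), size=size)
    best = max(idx, key=lambda i: (fitnesses[i], -len(population[i])))
    return population[int(best)]


def run_ga(ratios, y, cfg: GAConfig | None = None):
    """Run independent GA searches; return the final population of each run.

    Each run uses seed ``cfg.seed + run_index`` for all of its stochasticity
    (including its fitness CV splits, which are fixed within a run so cached
    fitness values are exact). Elitism guarantees that the best fitness in
    the population never decreases across generations.

    Returns
    -------
    list (one entry per run) of lists of (subset, fitness) for every
    final-generation individual.
    """
    if cfg is None:
        cfg = GAConfig()
    X = _ratio_matrix(ratios)
    if not np.all(np.isfinite(X)):
        raise ValueError("ratio matrix contains non-finite values")
    n_ratios = X.shape[1]
    kmin, kmax = cfg.subset_size_range
    if kmin > n_ratios:
        raise ValueError("subset_size_range minimum exceeds the number of ratios")

    all_runs = []
    for run in range(cfg.n_ga_runs):
        run_seed = cfg.seed + run
        rng = np.random.default_rng(run_seed)
        fitness = _Fitness(X, y, cfg.fitness_cv_folds, cfg.fitness_cv_repeats, run_seed)
        population = [
            _random_subset(rng, n_ratios, kmin, kmax)
            for _ in range(cfg.population_size)
        ]
        best_so_far = -np.inf
        for _ in range(cfg.n_generations):
            fits = [fitness(ind) for ind in population]
            gen_best = max(fits)
            # elitism makes best fitness monotone non-decreasing
            assert gen_best >= best_so_far - 1e-12
            best_so_far = max(best_so_far, gen_best)
            order = sorted(
                range(len(population)), key=lambda i: (fits[i], -len(population[i])),
                reverse=True,
            )
            next_pop = [population[i] for i in order[: cfg.elitism]]
            while len(next_pop) < cfg.population_size:
                p1 = _tournament(rng, population, fits, cfg.tournament_size)
                p2 = _tournament(rng, population, fits, cfg.tournament_size)
                if rng.random() < cfg.crossover_prob:
                    c1, c2 = _crossover(rng, p1, p2, kmin, kmax)
                else:
                    c1, c2 = p1, p2
                for child in (c1, c2):
                    if rng.random() < cfg.mutation_prob:
                        child = _mutate(rng, child, n_ratios, kmin, kmax)
                    assert kmin <= len(child) <= kmax
                    next_pop.append(child)
                    if len(next_pop) == cfg.population_size:
                        break
            population = next_pop
        final_fits = [fitness(ind) for ind in population]
        all_runs.append(list(zip(population, final_fits)))
    return all_runs


def _distinct_solutions(final_populations):
    seen = {}
    for run in final_populations:
        for subset, fit in run:
            if subset not in seen:
                seen[subset] = fit
    return seen


def evaluate_solution(subset, learn, valid, seed: int = 0, n_cv_repeats: int = 30):
    """Three-way evaluation of one ratio subset.

    Returns (learning_accuracy, cv_accuracy, validation_accuracy): training
    accuracy of an LDA fit on the full learning set, mean of ``n_cv_repeats``
    stratified 2-fold CV repeats on the learning set, and the learning-fit
    model's accuracy on the validation set.
    """
    X_learn, y_learn = learn
    X_valid, y_valid = valid
    cols = list(subset)
    Xl = _ratio_matrix_cols(X_learn, cols)
    Xv = _ratio_matrix_cols(X_valid, cols)
    model = fit_lda(Xl, y_learn)
    learning_acc = accuracy(y_learn, predict(model, Xl))
    y = np.asarray(y_learn)
    _, y_codes = np.unique(y, return_inverse=True)
    splits = stratified_splits(y, 2, n_cv_repeats, seed)
    cv_acc = float(
        _cv_accuracy(np.asarray(Xl, float), y_codes, int(y_codes.max()) + 1, splits).mean()
    )
    valid_acc = accuracy(y_valid, predict(model, Xv))
    return learning_acc, cv_acc, valid_acc


def _ratio_matrix_cols(X, cols):
    X = _ratio_matrix(X)
    return X[:, cols]


def rank_and_select(
    final_populations,
    learn,
    valid,
    pairs: list[tuple[int, int]] | None = None,
    pair_labels: list[str] | None = None,
    seed: int = 0,
    n_cv_repeats: int = 30,
    accuracy_floor: float = 0.80,
) -> GASolution:
    """Multi-stage ranking of all final-generation GA solutions.

    1. Every distinct solution is re-scored by ``n_cv_repeats``-repeat
       stratified 2-fold CV on the learning set (one shared set of splits,
       so scores are comparable).
    2. Solutions above ``accuracy_floor`` survive.
    3. Each survivor's LDA, fit on the whole learning set, is scored on the
       independent validation set.
    4. The winner maximizes validation accuracy; ties break toward fewest
       distinct molecules, then fewest ratios, then highest CV accuracy.

    If nothing clears the floor, the best-by-CV solution is returned with a
    prominent warning.
    """
    X_learn, y_learn = learn
    X_valid, y_valid = valid
    Xl = _ratio_matrix(X_learn)
    Xv = _ratio_matrix(X_valid)
    y = np.asarray(y_learn)
    _, y_codes = np.unique(y, return_inverse=True)
    n_classes = int(y_codes.max()) + 1
    splits = stratified_splits(y, 2, n_cv_repeats, seed)

    candidates = _distinct_solutions(final_populations)
    if not candidates:
        raise ValueError("no GA solutions to rank")

    cv_scores = {
        subset: float(
            _cv_accuracy(Xl[:, list(subset)], y_codes, n_classes, splits).mean()
        )
        for subset in candidates
    }
    survivors = [s for s, v in cv_scores.items() if v > accuracy_floor]
    if not survivors:
        warnings.warn(
            "no GA solution exceeded the CV accuracy floor "
            f"({accuracy_floor:.0%}); returning the best-by-CV solution",
            stacklevel=2,
        )
        survivors = [max(cv_scores, key=lambda s: (cv_scores[s], -len(s)))]

    def n_molecules(subset) -> int:
        if pairs is None:
            return 2 * len(subset)
        return len({f for k in subset for f in pairs[k]})

    scored = []
    for subset in survivors:
        cols = list(subset)
        model = fit_lda(Xl[:, cols], y_learn)
        val_acc = accuracy(y_valid, predict(model, Xv[:, cols]))
        learn_acc = accuracy(y_learn, predict(model, Xl[:, cols]))
        scored.append((subset, val_acc, learn_acc))

    best = max(
        scored,
        key=lambda t: (t[1], -n_molecules(t[0]), -len(t[0]), cv_scores[t[0]]),
    )
    subset, val_acc, learn_acc = best
    sel_pairs = [pairs[k] for k in subset] if pairs is not None else []
    sel_labels = [pair_labels[k] for k in subset] if pair_labels is not None else []
    return GASolution(
        ratio_indices=subset,
        ratio_pairs=sel_pairs,
        fitness=candidates[subset],
        learning_accuracy=learn_acc,
        cv30_accuracy=cv_scores[subset],
        validation_accuracy=val_acc,
        n_molecules=n_molecules(subset),
        pair_labels=sel_labels,
    )
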