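"""GA subset search, multi-stage ranking, and solution evaluation."""

import numpy as np
import pytest

import ionratio as ir


def _split_ratios(cohort, seed=0):
    matrix, truth = cohort
    learn, valid = ir.split_learning_validation(matrix, 5, seed=seed)
    rl, rv = ir.build_ratios(learn), ir.build_ratios(valid)
    return rl, rv, np.asarray(rl.class_labels), np.asarray(rv.class_labels), truth


SMALL_GA = dict(population_size=60, n_generations=25, n_ga_runs=4, mutation_prob=0.4)


class TestRunGA:
    def test_deterministic(self, small_cohort):
        rl, _, y, _, _ = _split_ratios(small_cohort)
        cfg = ir.GAConfig(seed=1, **SMALL_GA)
        f1 = ir.run_ga(rl, y, cfg)
        f2 = ir.run_ga(rl, y, cfg)
        assert f1 == f2

    def test_size_bounds_respected(self, small_cohort):
        rl, _, y, _, _ = _split_ratios(small_cohort)
        cfg = ir.GAConfig(subset_size_range=(2, 4), seed=2, **SMALL_GA)
        finals = ir.run_ga(rl, y, cfg)
        assert len(finals) == cfg.n_ga_runs
        for run in finals:
            assert len(run) == cfg.population_size
            for subset, fit in run:
                assert 2 <= len(subset) <= 4
                assert 0.0 <= fit <= 1.0
                assert list(subset) == sorted(set(subset))

    def test_best_fitness_monotone_in_generations(self, small_cohort):
        # runs with the same seed share their evolution trajectory as a
        # prefix, so elitism makes the best final fitness non-decreasing in
        # the generation count
        rl, _, y, _, _ = _split_ratios(small_cohort)
        best = []
        for gens in (1, 5, 15):
            cfg = ir.GAConfig(
                population_size=40, n_generations=gens, n_ga_runs=1, seed=3
            )
            finals = ir.run_ga(rl, y, cfg)
            best.append(max(fit for _, fit in finals[0]))
        assert best == sorted(best)

    def test_recovers_planted_pair(self, small_cohort):
        rl, rv, y, yv, truth = _split_ratios(small_cohort)
        cfg = ir.GAConfig(seed=5, **SMALL_GA)
        finals = ir.run_ga(rl, y, cfg)
        sol = ir.rank_and_select(
            finals,
            (rl.ratio_matrix, y),
            (rv.ratio_matrix, yv),
            pairs=rl.pairs,
            pair_labels=rl.pair_labels,
            seed=6,
        )
        planted = {
            frozenset((p.numerator, p.denominator)) for p in truth
        }
        assert any(frozenset(p) in planted for p in sol.ratio_pairs)
        assert sol.validation_accuracy >= 0.8

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ir.GAConfig(subset_size_range=(0, 5))
        with pytest.raises(ValueError):
            ir.GAConfig(mutation_prob=1.5)
        with pytest.raises(ValueError):
            ir.GAConfig(population_size=2, elitism=2)

    def test_non_finite_ratios_rejected(self):
        X = np.array([[1.0, np.inf], [1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        with pytest.raises(ValueError):
            ir.run_ga(X, ["A", "A", "B", "B"], ir.GAConfig())


class TestRankAndSelect:
    def _crafted(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["A", "B", "C"], 10)
        codes = np.repeat([0.0, 1.0, 2.0], 10)

        def make(n):
            X = np.empty((n * 3, 3))
            c = np.repeat([0.0, 1.0, 2.0], n)
            X[:, 0] = c + rng.normal(0, 0.05, n * 3)  # strong separator
            X[:, 1] = c + rng.normal(0, 0.05, n * 3)  # strong separator
            X[:, 2] = rng.normal(0, 1, n * 3)         # noise
            return X, np.repeat(["A", "B", "C"], n)

        Xl, yl = make(10)
        Xv, yv = make(10)
        assert list(yl) == list(y) and codes.size == 30
        return Xl, yl, Xv, yv

    def test_ties_break_to_fewest_molecules(self):
        Xl, yl, Xv, yv = self._crafted()
        finals = [[((0,), 1.0), ((0, 1), 1.0), ((2,), 0.4)]]
        pairs = [(0, 1), (2, 3), (4, 5)]
        sol = ir.rank_and_select(
            finals, (Xl, yl), (Xv, yv), pairs=pairs, seed=0
        )
        # (0,) and (0, 1) both classify perfectly; fewest molecules wins
        assert sol.ratio_indices == (0,)
        assert sol.n_molecules == 2
        assert sol.validation_accuracy == 1.0

    def test_floor_failure_warns_and_falls_back(self):
        rng = np.random.default_rng(1)
        Xl = rng.lognormal(0, 1, (30, 2))
        Xv = rng.lognormal(0, 1, (30, 2))
        y = np.repeat(["A", "B", "C"], 10)
        finals = [[((0,), 0.3), ((1,), 0.35)]]
        with pytest.warns(UserWarning, match="accuracy floor"):
            sol = ir.rank_and_select(
                finals, (Xl, y), (Xv, y), pairs=[(0, 1), (1, 0)], seed=0
            )
        assert sol.cv30_accuracy is not None

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            ir.rank_and_select([[]], (np.ones((4, 1)), ["A", "A", "B", "B"]),
                               (np.ones((2, 1)), ["A", "B"]))


class TestEvaluateSolution:
    def test_planted_solution_scores(self, small_cohort):
        rl, rv, y, yv, truth = _split_ratios(small_cohort)
        k = rl.pairs.index((truth[0].numerator, truth[0].denominator))
        learn_acc, cv_acc, val_acc = ir.evaluate_solution(
            (k,), (rl.ratio_matrix, y), (rv.ratio_matrix, yv), seed=0
        )
        assert learn_acc >= 0.9
        assert val_acc >= 0.8
        assert 0.0 <= cv_acc <= 1.0

    def test_learning_exceeds_cv_on_pure_noise(self):
        # training accuracy is optimistically biased; repeated CV is not
        rng = np.random.default_rng(4)
        Xl = rng.lognormal(0, 1, (30, 6))
        Xv = rng.lognormal(0, 1, (30, 6))
        y = np.repeat(["A", "B", "C"], 10)
        learn_acc, cv_acc, _ = ir.evaluate_solution(
            (0, 1, 2), (Xl, y), (Xv, y), seed=0
        )
        assert learn_acc > cv_acc
        assert cv_acc == pytest.approx(1 / 3, abs=0.2)
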