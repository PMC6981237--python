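"""Behaviour of the synthetic cohort and spectrum generators."""

import numpy as np
import pytest

import ionratio as ir
from ionratio.preprocessing import ConfigError


class TestSimulateCohort:
    def test_deterministic_for_fixed_seed(self):
        cfg = ir.CohortSimConfig(n_peaks=20, n_samples_per_class=5, seed=3)
        m1, t1 = ir.simulate_cohort(cfg)
        m2, t2 = ir.simulate_cohort(cfg)
        np.testing.assert_array_equal(m1.intensities, m2.intensities)
        np.testing.assert_array_equal(m1.feature_mz, m2.feature_mz)
        assert [(p.numerator, p.denominator) for p in t1] == [
            (p.numerator, p.denominator) for p in t2
        ]

    def test_shapes_and_labels(self):
        cfg = ir.CohortSimConfig(
            n_classes=3, n_samples_per_class=4, n_replicates=2, n_peaks=12, seed=0
        )
        m, truth = ir.simulate_cohort(cfg, average=False)
        assert m.intensities.shape == (3 * 4 * 2, 12)
        assert m.replicate_ids is not None
        assert sorted(set(m.class_labels)) == ["A", "B", "C"]
        avg, _ = ir.simulate_cohort(cfg, average=True)
        assert avg.intensities.shape == (12, 12)
        assert avg.replicate_ids is None
        assert len(truth) == cfg.n_discriminant_ratio_pairs

    def test_intensities_positive(self):
        m, _ = ir.simulate_cohort(ir.CohortSimConfig(n_peaks=30, seed=1))
        assert np.all(m.intensities > 0)

    def test_ratios_invariant_to_per_row_scaling(self):
        # the generator's injection factor is a per-row scalar; scaling rows
        # again must leave every pairwise ratio untouched
        m, _ = ir.simulate_cohort(
            ir.CohortSimConfig(n_peaks=8, n_samples_per_class=5, seed=2)
        )
        base = ir.build_ratios(m).ratio_matrix
        rng = np.random.default_rng(0)
        scaled = ir.AlignedMatrix(
            sample_ids=m.sample_ids,
            class_labels=m.class_labels,
            feature_mz=m.feature_mz,
            intensities=m.intensities * rng.uniform(0.1, 10, m.n_samples)[:, None],
        )
        np.testing.assert_allclose(ir.build_ratios(scaled).ratio_matrix, base)

    def test_planted_ratio_t_statistic_dominates(self):
        # 2 classes so a two-sample t statistic is well-defined; the planted
        # ratio's |t| must exceed >= 95% of all other ratios'
        cfg = ir.CohortSimConfig(
            n_classes=2,
            n_samples_per_class=50,
            n_peaks=30,
            n_discriminant_ratio_pairs=1,
            ratio_effect_size=2.0,
            seed=7,
        )
        m, truth = ir.simulate_cohort(cfg)
        rs = ir.build_ratios(m, log_ratios=True)
        y = np.asarray(rs.class_labels)
        a = rs.ratio_matrix[y == "A"]
        b = rs.ratio_matrix[y == "B"]
        t = np.abs(a.mean(0) - b.mean(0)) / np.sqrt(
            a.var(0, ddof=1) / len(a) + b.var(0, ddof=1) / len(b)
        )
        planted = {(p.numerator, p.denominator) for p in truth}
        planted |= {(p.denominator, p.numerator) for p in truth}
        planted_t = min(t[k] for k, pr in enumerate(rs.pairs) if pr in planted)
        others = [t[k] for k, pr in enumerate(rs.pairs) if pr not in planted]
        assert planted_t >= np.quantile(others, 0.95)

    def test_empirical_class_ratio_means(self):
        # geometric mean of the planted ratio per class tracks the declared
        # class_ratio_means (log-normal noise is median-unbiased)
        cfg = ir.CohortSimConfig(
            n_peaks=10, n_samples_per_class=200, ratio_effect_size=2.0, seed=11
        )
        m, truth = ir.simulate_cohort(cfg)
        y = np.asarray(m.class_labels)
        for p in truth:
            ratio = m.intensities[:, p.numerator] / m.intensities[:, p.denominator]
            for c, lab in enumerate(sorted(set(y))):
                gmean = np.exp(np.mean(np.log(ratio[y == lab])))
                assert gmean == pytest.approx(p.class_ratio_means[c], rel=0.1)

    def test_adjacent_class_step_is_effect_size(self):
        _, truth = ir.simulate_cohort(
            ir.CohortSimConfig(n_peaks=10, ratio_effect_size=2.5, seed=4)
        )
        for p in truth:
            steps = p.class_ratio_means[1:] / p.class_ratio_means[:-1]
            # the rotated score pattern makes one wrap-around step; every
            # other adjacent step is exactly the effect size
            assert np.sum(np.isclose(steps, 2.5)) >= len(steps) - 1

    def test_null_effect_gives_flat_class_means(self):
        _, truth = ir.simulate_cohort(
            ir.CohortSimConfig(n_peaks=10, ratio_effect_size=1.0, seed=5)
        )
        for p in truth:
            assert np.allclose(p.class_ratio_means, p.class_ratio_means[0])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_classes": 1},
            {"n_peaks": 3, "n_discriminant_ratio_pairs": 2},
            {"ratio_effect_size": 0.0},
            {"intensity_noise_cv": -0.1},
            {"n_replicates": 0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ConfigError):
            ir.CohortSimConfig(**kwargs)


class TestSplit:
    def test_stratified_and_disjoint(self):
        m, _ = ir.simulate_cohort(
            ir.CohortSimConfig(n_peaks=8, n_samples_per_class=20, seed=0)
        )
        learn, valid = ir.split_learning_validation(m, 10, seed=1)
        for part in (learn, valid):
            labs, counts = np.unique(part.class_labels, return_counts=True)
            assert list(labs) == ["A", "B", "C"]
            assert all(c == 10 for c in counts)
        assert set(learn.sample_ids).isdisjoint(valid.sample_ids)

    def test_too_few_samples(self):
        m, _ = ir.simulate_cohort(
            ir.CohortSimConfig(n_peaks=8, n_samples_per_class=5, seed=0)
        )
        with pytest.raises(ValueError):
            ir.split_learning_validation(m, 5, seed=0)


class TestCohortToSpectra:
    def test_scan_sum_reconstructs_row_intensity(self):
        m, _ = ir.simulate_cohort(
            ir.CohortSimConfig(
                n_peaks=5, n_samples_per_class=1, n_replicates=1,
                mz_range=(200.0, 260.0), seed=6,
            )
        )
        specs = ir.cohort_to_spectra(
            m, n_scans=10, baseline_level=0.0, noise_sd=0.0, mz_jitter_sd=0.0, seed=0
        )
        assert len(specs) == m.n_samples
        spec = specs[0]
        mz, summed = ir.sum_scan_window(spec, (0, 9))
        for j, center in enumerate(m.feature_mz):
            window = np.abs(mz - center) < 0.1
            # the true center can fall between grid points, costing up to
            # exp(-0.5 (step/2 / sigma)^2) ~ 3% of the apex height
            assert summed[window].max() == pytest.approx(
                m.intensities[0, j], rel=0.05
            )


class TestCompoundDB:
    def test_covers_requested_fraction_within_ppm(self):
        mz = np.linspace(200, 700, 40)
        db, covered = ir.make_compound_db(mz, annotated_fraction=0.5, seed=0)
        assert len(covered) == 20
        for i in covered:
            errs = np.abs((db.theoretical_mz - mz[i]) / db.theoretical_mz * 1e6)
            assert errs.min() < 10.0
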