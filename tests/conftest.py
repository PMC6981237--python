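import numpy as np
import pytest

import ionratio as ir


@pytest.fixture
def gaussian_spectrum():
    """One noiseless Gaussian peak on a zero baseline, 10 scans."""
    cfg = ir.SpectrumSimConfig(
        n_scans=10,
        mz_range=(100.0, 120.0),
        peak_centers=[110.0],
        peak_heights=[1e6],
        peak_width_sigma=0.1,
        grid_step=0.01,
        seed=0,
    )
    return ir.simulate_spectrum(cfg)


@pytest.fixture
def small_cohort():
    """Small 3-class cohort with one planted ratio pair."""
    cfg = ir.CohortSimConfig(
        n_peaks=10,
        n_samples_per_class=10,
        n_discriminant_ratio_pairs=1,
        ratio_effect_size=3.0,
        seed=42,
    )
    return ir.simulate_cohort(cfg)


@pytest.fixture
def separable_xy():
    """Three well-separated 2-D Gaussian classes."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([rng.normal(c, 0.3, size=(20, 2)) for c in centers])
    y = np.repeat(["A", "B", "C"], 20)
    return X, y
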