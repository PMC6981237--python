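"""Synthetic spectra and class-structured cohorts for the ratio workflow.

Two generators:

* :func:`simulate_spectrum` — multi-scan profile spectra (Gaussian peaks on a
  drifting linear baseline plus i.i.d. noise) for exercising preprocessing.
* :func:`simulate_cohort` — an aligned intensity matrix for a multi-class
  sample set in which a few *planted* peak-intensity ratios separate the
  classes while absolute intensities fluctuate freely from injection to
  injection. This emulates the regime the ratio representation is designed
  for: ion abundances vary per injection, their ratios stay stable.

The class signal of a planted pair (i, j) is split multiplicatively between
its two peaks — numerator mean x effect^(+s_c/2), denominator mean x
effect^(-s_c/2) for a centred class score s_c — so the planted *ratio* mean
moves by exactly ``ratio_effect_size`` per class step while any ratio sharing
only one planted peak carries half the log-effect; each planted pair uses a
rotated class-score pattern so that peaks from different pairs never combine
into an equally strong ratio. Variability has three log-normal components:
biological variation between samples of one class (shared by a sample's
technical replicates), a per-injection global scale factor, and per-peak
technical noise — intensities stay positive and pairwise ratios are exactly
invariant to the injection factor. Ground truth (the planted pairs and their
class means) is returned alongside the data so recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedMatrix, average_replicates
from .preprocessing import ConfigError, RawSpectrum

__all__ = [
    "SpectrumSimConfig",
    "CohortSimConfig",
    "PlantedPair",
    "simulate_spectrum",
    "simulate_cohort",
    "cohort_to_spectra",
    "make_compound_db",
    "split_learning_validation",
]


@dataclass
class SpectrumSimConfig:
    """Configuration for one simulated multi-scan spectrum."""

    n_scans: int = 10
    mz_range: tuple[float, float] = (100.0, 1000.0)
    peak_centers: list[float] = field(default_factory=list)
    peak_heights: list[float] = field(default_factory=list)
    peak_width_sigma: float = 0.05
    baseline_level: float = 0.0
    baseline_drift_slope: float = 0.0
    noise_sd: float = 0.0
    grid_step: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not lo < hi:
            raise ConfigError("mz_range: low must be < high")
        if self.n_scans < 1:
            raise ConfigError("n_scans: must be >= 1")
        if len(self.peak_centers) != len(self.peak_heights):
            raise ConfigError("peak_centers: must match peak_heights in length")
        if any(not lo <= c <= hi for c in self.peak_centers):
            raise ConfigError("peak_centers: must lie within mz_range")
        if any(h < 0 for h in self.peak_heights):
            raise ConfigError("peak_heights: must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        if self.peak_width_sigma <= 0:
            raise ConfigError("peak_width_sigma: must be > 0")
        if self.grid_step <= 0:
            raise ConfigError("grid_step: must be > 0")


def simulate_spectrum(
    cfg: SpectrumSimConfig, sample_id: str = "sim", replicate_id: str = "r1"
) -> RawSpectrum:
    """Simulate a multi-scan profile spectrum on a uniform m/z grid.

    Every scan is the same deterministic signal — Gaussian peaks plus a
    linear baseline — with fresh i.i.d. Gaussian noise; intensities are
    clipped at zero. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_range
    mz = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    signal = cfg.baseline_level + cfg.baseline_drift_slope * (mz - lo)
    for c, h in zip(cfg.peak_centers, cfg.peak_heights):
        signal = signal + h * np.exp(-0.5 * ((mz - c) / cfg.peak_width_sigma) ** 2)
    scans = np.tile(signal, (cfg.n_scans, 1))
    if cfg.noise_sd > 0:
        scans = scans + rng.normal(0.0, cfg.noise_sd, size=scans.shape)
    return RawSpectrum(sample_id, replicate_id, mz, np.clip(scans, 0.0, None))


@dataclass
class CohortSimConfig:
    """Configuration for a class-structured aligned-intensity cohort.

    Defaults mirror a three-region study design with technical triplicates.
    ``ratio_effect_size`` is the multiplicative step between adjacent class
    means of each planted ratio; ``injection_scale_sd`` the log-scale sd of
    the per-injection global factor; ``intensity_noise_cv`` the per-peak
    coefficient of variation.
    """

    n_classes: int = 3
    n_samples_per_class: int = 20
    n_replicates: int = 3
    n_peaks: int = 72
    n_discriminant_ratio_pairs: int = 2
    ratio_effect_size: float = 2.0
    injection_scale_sd: float = 0.5
    intensity_noise_cv: float = 0.15
    technical_noise_cv: float = 0.05
    pair_covariation_sd: float = 0.5
    mz_range: tuple[float, float] = (150.0, 800.0)
    base_intensity_range: tuple[float, float] = (1e5, 1e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("n_classes: must be >= 2")
        if self.n_samples_per_class < 1:
            raise ConfigError("n_samples_per_class: must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates: must be >= 1")
        if 2 * self.n_discriminant_ratio_pairs > self.n_peaks:
            raise ConfigError(
                "n_discriminant_ratio_pairs: needs 2 peaks per pair within n_peaks"
            )
        if self.injection_scale_sd < 0:
            raise ConfigError("injection_scale_sd: must be >= 0")
        if self.intensity_noise_cv < 0:
            raise ConfigError("intensity_noise_cv: must be >= 0")
        if self.technical_noise_cv < 0:
            raise ConfigError("technical_noise_cv: must be >= 0")
        if self.pair_covariation_sd < 0:
            raise ConfigError("pair_covariation_sd: must be >= 0")
        if self.ratio_effect_size <= 0:
            raise ConfigError("ratio_effect_size: must be > 0")


@dataclass
class PlantedPair:
    """Ground truth for one planted discriminant ratio."""

    numerator: int
    denominator: int
    class_ratio_means: np.ndarray  # expected ratio mean per class


def _class_labels(n_classes: int) -> list[str]:
    return [chr(ord("A") + c) for c in range(n_classes)]


def simulate_cohort(
    cfg: CohortSimConfig, average: bool = True
) -> tuple[AlignedMatrix, list[PlantedPair]]:
    """Simulate an aligned samples x peaks matrix with planted ratio signals.

    Each injection's row is the per-peak base mean, shifted for planted peaks
    according to the sample's class, then multiplied by a log-normal
    per-injection global factor and per-peak log-normal noise (both mean 1).
    With ``average`` the technical replicates are arithmetically averaged into
    one row per biological sample (the form downstream stages consume);
    otherwise the replicate-level matrix is returned.
    """
    rng = np.random.default_rng(cfg.seed)
    K, npc, nrep, p = (
        cfg.n_classes,
        cfg.n_samples_per_class,
        cfg.n_replicates,
        cfg.n_peaks,
    )
    labels = _class_labels(K)

    lo, hi = cfg.mz_range
    peak_mz = np.sort(rng.uniform(lo, hi, size=p))
    blo, bhi = cfg.base_intensity_range
    base = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=p))

    planted_idx = rng.choice(p, size=2 * cfg.n_discriminant_ratio_pairs, replace=False)
    pairs = [
        (int(planted_idx[2 * k]), int(planted_idx[2 * k + 1]))
        for k in range(cfg.n_discriminant_ratio_pairs)
    ]

    # centred class scores: adjacent classes differ by 1. Each planted pair
    # uses a rotated score pattern so that cross-combinations of peaks from
    # different pairs carry at most half the log-effect and the planted pairs
    # themselves remain the uniquely strongest ratios.
    s = np.arange(K, dtype=float) - (K - 1) / 2.0
    log_e = np.log(cfg.ratio_effect_size)
    pair_scores = [np.roll(s, k % K) for k in range(len(pairs))]
    # per-class multiplicative shift per peak (identity for non-planted peaks)
    shift = np.ones((K, p))
    for (num, den), s_k in zip(pairs, pair_scores):
        shift[:, num] = np.exp(+0.5 * s_k * log_e)
        shift[:, den] = np.exp(-0.5 * s_k * log_e)

    # biological variation differs between samples of one class and is shared
    # by a sample's technical replicates; technical noise and the injection
    # factor are drawn fresh per injection. Both log-normal with mean 1.
    sigma_bio = np.sqrt(np.log1p(cfg.intensity_noise_cv**2))
    sigma_tech = np.sqrt(np.log1p(cfg.technical_noise_cv**2))
    n_rows = K * npc * nrep
    sample_ids, replicate_ids, class_labels = [], [], []
    X = np.empty((n_rows, p))
    row = 0
    for c in range(K):
        for sidx in range(npc):
            sid = f"{labels[c]}{sidx + 1:02d}"
            bio = np.exp(rng.normal(-0.5 * sigma_bio**2, sigma_bio, size=p))
            # planted peaks co-vary: a shared per-sample factor moves both
            # peaks of a pair together and cancels exactly in their ratio,
            # so neither peak is informative on its own
            for num, den in pairs:
                g = np.exp(rng.normal(0.0, cfg.pair_covariation_sd))
                bio[num] *= g
                bio[den] *= g
            for r in range(nrep):
                inj = np.exp(rng.normal(0.0, cfg.injection_scale_sd))
                tech = np.exp(
                    rng.normal(-0.5 * sigma_tech**2, sigma_tech, size=p)
                )
                X[row] = base * shift[c] * bio * inj * tech
                sample_ids.append(sid)
                replicate_ids.append(f"r{r + 1}")
                class_labels.append(labels[c])
                row += 1

    matrix = AlignedMatrix(
        sample_ids=sample_ids,
        class_labels=class_labels,
        feature_mz=peak_mz,
        intensities=X,
        replicate_ids=replicate_ids,
    )
    if average:
        matrix = average_replicates(matrix)

    truth = []
    for (num, den), s_k in zip(pairs, pair_scores):
        ratio_means = (base[num] / base[den]) * np.exp(s_k * log_e)
        truth.append(PlantedPair(num, den, ratio_means))
    return matrix, truth


def cohort_to_spectra(
    matrix: AlignedMatrix,
    n_scans: int = 60,
    peak_width_sigma: float = 0.04,
    grid_step: float = 0.02,
    mz_jitter_sd: float = 0.002,
    baseline_level: float = 2000.0,
    noise_sd: float = 200.0,
    seed: int = 0,
) -> list[RawSpectrum]:
    """Render each matrix row as a raw multi-scan spectrum.

    Peak heights are the row intensities divided by the number of scans (so
    the summed scan window reconstructs the row), peak positions get a small
    per-injection m/z jitter (what alignment must undo), and a constant
    baseline plus Gaussian noise is added. Used to exercise the full pipeline
    end to end.
    """
    rng = np.random.default_rng(seed)
    rep_ids = matrix.replicate_ids or ["r1"] * matrix.n_samples
    specs = []
    lo = matrix.feature_mz.min() - 5.0
    hi = matrix.feature_mz.max() + 5.0
    for i in range(matrix.n_samples):
        centers = matrix.feature_mz + rng.normal(0.0, mz_jitter_sd, matrix.n_features)
        cfg = SpectrumSimConfig(
            n_scans=n_scans,
            mz_range=(lo, hi),
            peak_centers=list(centers),
            peak_heights=list(matrix.intensities[i] / n_scans),
            peak_width_sigma=peak_width_sigma,
            baseline_level=baseline_level,
            noise_sd=noise_sd,
            grid_step=grid_step,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(
            simulate_spectrum(cfg, sample_id=matrix.sample_ids[i], replicate_id=rep_ids[i])
        )
    return specs


def make_compound_db(
    peak_mz: np.ndarray,
    annotated_fraction: float = 0.5,
    n_decoys: int = 30,
    mz_error_ppm_sd: float = 2.0,
    seed: int = 0,
):
    """Build a synthetic compound database covering part of a peak list.

    A fraction of the peaks get an entry whose theoretical mass deviates from
    the observed one by a small ppm-scale error; decoy entries fall at
    unrelated masses. Returns (CompoundDB, list of covered peak indices).
    """
    from .annotation import CompoundDB

    rng = np.random.default_rng(seed)
    peak_mz = np.asarray(peak_mz, dtype=float)
    p = peak_mz.size
    n_cov = max(2, int(round(annotated_fraction * p)))
    covered = sorted(rng.choice(p, size=min(n_cov, p), replace=False).tolist())
    names, masses = [], []
    for i in covered:
        err = rng.normal(0.0, mz_error_ppm_sd) * 1e-6
        names.append(f"compound_{i:03d}")
        masses.append(peak_mz[i] * (1.0 + err))
    lo, hi = peak_mz.min(), peak_mz.max()
    for j in range(n_decoys):
        names.append(f"decoy_{j:03d}")
        masses.append(float(rng.uniform(lo + 1.0, hi + 50.0)) + 0.31)
    return CompoundDB(names=names, theoretical_mz=np.asarray(masses)), covered


def split_learning_validation(
    matrix: AlignedMatrix, n_learning_per_class: int, seed: int = 0
) -> tuple[AlignedMatrix, AlignedMatrix]:
    """Stratified split of a cohort into learning and validation matrices."""
    rng = np.random.default_rng(seed)
    y = np.asarray(matrix.class_labels)
    learn_idx: list[int] = []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        if idx.size <= n_learning_per_class:
            raise ValueError(
                f"class {c!r} has {idx.size} samples; cannot hold any out"
            )
        learn_idx.extend(rng.permutation(idx)[:n_learning_per_class].tolist())
    learn_idx = sorted(learn_idx)
    valid_idx = sorted(set(range(matrix.n_samples)) - set(learn_idx))

    def take(rows):
        return AlignedMatrix(
            sample_ids=[matrix.sample_ids[i] for i in rows],
            class_labels=[matrix.class_labels[i] for i in rows],
            feature_mz=matrix.feature_mz,
            intensities=matrix.intensities[rows],
            replicate_ids=None
            if matrix.replicate_ids is None
            else [matrix.replicate_ids[i] for i in rows],
        )

    return take(learn_idx), take(valid_idx)
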