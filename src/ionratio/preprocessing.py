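"""Raw-spectrum preprocessing: scan summation, baseline removal, peak picking.

The pipeline works on profile-like spectra sampled on a shared m/z grid.
For each injection, scans covering the elution window of interest are summed
into one spectrum, the slowly varying chemical/electronic baseline is removed
by local regression through per-window minima, and peaks are extracted with a
smoothed-local-maximum detector validated by signal-to-noise and robust-spread
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "RawSpectrum",
    "PeakParams",
    "PeakTable",
    "sum_scan_window",
    "subtract_baseline",
    "detect_peaks",
]


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


@dataclass
class RawSpectrum:
    """Multi-scan profile spectrum for one injection on a shared m/z grid.

    Attributes
    ----------
    sample_id, replicate_id : str
        Identity of the biological sample and the technical replicate.
    mz : ndarray
        Strictly increasing m/z grid (Th), shared by all scans.
    intensities : ndarray, shape (n_scans, n_points)
        Non-negative intensity per scan on the shared grid.
    """

    sample_id: str
    replicate_id: str
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.mz.ndim != 1 or self.mz.size < 2:
            raise ConfigError("mz: need a 1-D grid with at least 2 points")
        if np.any(np.diff(self.mz) <= 0):
            raise ConfigError("mz: grid must be strictly increasing")
        if self.intensities.shape[0] < 1:
            raise ConfigError("intensities: need at least one scan")
        if self.intensities.shape[1] != self.mz.size:
            raise ConfigError("intensities: scan length does not match the m/z grid")
        if np.any(self.intensities < 0):
            raise ConfigError("intensities: negative intensity")

    @property
    def n_scans(self) -> int:
        return self.intensities.shape[0]

    @property
    def scans(self):
        """Iterate scans as (mz, intensity) pairs on the shared grid."""
        return [(self.mz, self.intensities[i]) for i in range(self.n_scans)]


@dataclass
class PeakParams:
    """Peak-detection parameters.

    ``span`` is the width (in grid points) of both the moving-average smoother
    and the local-maximum / validation window; ``sm_span`` is the half-width of
    the neighbourhood excluded around a candidate when estimating local noise;
    ``zerothrsh`` is an absolute intensity floor; ``son`` the required
    signal-to-noise ratio; ``mad_mult`` the required multiple of the robust
    spread (MAD) of the smoothed signal in the window. ``area_w`` is accepted
    for interface fidelity but inert: peak areas are not used downstream.
    """

    span: int = 5
    sm_span: int = 1
    zerothrsh: float = 20000.0
    area_w: float = 0.05
    son: float = 1.5
    mad_mult: float = 1.64
    baseline_bandwidth: float = 0.1
    scan_window: tuple[int, int] = (240, 295)

    def __post_init__(self) -> None:
        if self.span < 3 or self.span % 2 == 0:
            raise ConfigError("span: must be odd and >= 3")
        if self.sm_span < 0:
            raise ConfigError("sm_span: must be >= 0")
        if self.son <= 0:
            raise ConfigError("son: must be > 0")
        if not 0 < self.baseline_bandwidth <= 1:
            raise ConfigError("baseline_bandwidth: must be in (0, 1]")
        if self.zerothrsh < 0:
            raise ConfigError("zerothrsh: must be >= 0")


@dataclass
class PeakTable:
    """Detected peaks for one spectrum: apex m/z and (smoothed) height."""

    sample_id: str
    replicate_id: str
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    height: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.mz.shape != self.height.shape:
            raise ValueError("mz and height must have the same length")
        if self.mz.size:
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError("peaks must be sorted by strictly increasing m/z")
            if np.any(self.height <= 0):
                raise ValueError("peak heights must be > 0")

    def __len__(self) -> int:
        return self.mz.size


def sum_scan_window(spec: RawSpectrum, window: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Sum scan intensities over an inclusive scan-index window.

    Emulates extracting a compound-class spectrum from the total-ion-current
    trace by summing the scans spanning the elution range of interest.

    Returns
    -------
    (mz, summed) : the shared grid and the elementwise scan sum.
    """
    first, last = window
    if first < 0 or last >= spec.n_scans or first > last:
        raise IndexError(
            f"scan window {window} out of range for {spec.n_scans} scans"
        )
    return spec.mz, spec.intensities[first : last + 1].sum(axis=0)


def subtract_baseline(
    mz: np.ndarray,
    intensity: np.ndarray,
    bandwidth: float = 0.1,
    breaks: int = 200,
) -> np.ndarray:
    """Remove a slowly varying baseline by local regression.

    The spectrum's m/z range is divided into ``breaks`` equal intervals; the
    minimum intensity in each interval anchors the baseline, and a lowess fit
    with span ``bandwidth`` (fraction of the m/z range) smooths the anchors.
    Taking interval minima keeps genuine peaks out of the baseline, so narrow
    peaks survive subtraction at essentially full height.

    Returns the baseline-subtracted intensity, floored at 0.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have the same shape")
    if mz.size < 10:
        raise ValueError("need at least 10 points to estimate a baseline")
    n_breaks = max(4, min(breaks, mz.size // 2))
    edges = np.linspace(mz[0], mz[-1], n_breaks + 1)
    idx = np.clip(np.searchsorted(edges, mz, side="right") - 1, 0, n_breaks - 1)
    anchor_mz = np.empty(n_breaks)
    anchor_val = np.empty(n_breaks)
    keep = np.zeros(n_breaks, dtype=bool)
    for b in range(n_breaks):
        members = np.nonzero(idx == b)[0]
        if members.size == 0:
            continue
        j = members[np.argmin(intensity[members])]
        anchor_mz[b] = mz[j]
        anchor_val[b] = intensity[j]
        keep[b] = True
    anchor_mz, anchor_val = anchor_mz[keep], anchor_val[keep]
    if anchor_mz.size < 3:
        baseline = np.full_like(intensity, anchor_val.min())
    else:
        smooth = lowess(
            anchor_val, anchor_mz, frac=max(bandwidth, 3 / anchor_mz.size),
            it=2, return_sorted=False,
        )
        baseline = np.interp(mz, anchor_mz, smooth)
    return np.maximum(intensity - baseline, 0.0)


def _scaled_mad(x: np.ndarray) -> float:
    """Median absolute deviation scaled to estimate a Gaussian sigma."""
    if x.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    params: PeakParams | None = None,
    sample_id: str = "",
    replicate_id: str = "",
) -> PeakTable:
    """Detect and validate peaks in a baseline-subtracted spectrum.

    The signal is smoothed with a moving average over ``span`` nearest
    neighbours. Local maxima of the smoothed signal within each span-wide
    window become candidates. A candidate of smoothed height ``h`` at apex
    ``i`` is validated iff

    1. ``h >= zerothrsh`` (absolute intensity floor),
    2. ``h >= son * noise``, where the local noise is the scaled MAD of the
       smoothing residual (raw − smoothed) over the window points excluding
       the candidate and its ``sm_span`` nearest neighbours, and
    3. ``h > mad_mult * MAD(smoothed signal in the window)``.

    Heights are reported from the smoothed signal at the apex; ties between
    adjacent equal maxima keep the lowest-m/z grid point.
    """
    if params is None:
        params = PeakParams()
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        return PeakTable(sample_id, replicate_id)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have the same shape")

    span = max(3, params.span)
    half = span // 2
    smoothed = uniform_filter1d(intensity, size=span, mode="nearest")
    resid = intensity - smoothed

    # Local maxima over a span-wide window; among runs of equal maxima keep
    # the first (lowest-m/z) index.
    winmax = maximum_filter1d(smoothed, size=span, mode="nearest")
    cand = np.nonzero(smoothed >= winmax)[0]

    n = mz.size
    apex_idx: list[int] = []
    heights: list[float] = []
    last_kept = -10 * span
    for i in cand:
        h = smoothed[i]
        if i - last_kept <= half and apex_idx and smoothed[last_kept] == h:
            continue  # later member of a tied plateau
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = np.arange(lo, hi)
        if h < params.zerothrsh:
            continue
        other = window[np.abs(window - i) > params.sm_span]
        noise = _scaled_mad(resid[other])
        if h < params.son * noise:
            continue
        if not h > params.mad_mult * _scaled_mad(smoothed[window]):
            continue
        apex_idx.append(int(i))
        heights.append(float(h))
        last_kept = int(i)

    if not apex_idx:
        return PeakTable(sample_id, replicate_id)
    order = np.argsort(mz[apex_idx])
    peak_mz = mz[apex_idx][order]
    peak_h = np.asarray(heights)[order]
    uniq, first = np.unique(peak_mz, return_index=True)
    if uniq.size != peak_mz.size:
        warnings.warn("duplicate apex m/z values collapsed", stacklevel=2)
        peak_mz, peak_h = peak_mz[first], peak_h[first]
    return PeakTable(sample_id, replicate_id, peak_mz, peak_h)


def preprocess_spectrum(
    spec: RawSpectrum, params: PeakParams | None = None
) -> PeakTable:
    """Full per-injection preprocessing: sum scans, remove baseline, pick peaks.

    The scan window is clipped to the scans actually present so that short
    test spectra run through the same code path as full acquisitions.
    """
    if params is None:
        params = PeakParams()
    first, last = params.scan_window
    first = min(max(0, first), spec.n_scans - 1)
    last = min(last, spec.n_scans - 1)
    mz, summed = sum_scan_window(spec, (first, last))
    cleaned = subtract_baseline(mz, summed, params.baseline_bandwidth)
    return detect_peaks(mz, cleaned, params, spec.sample_id, spec.replicate_id)
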