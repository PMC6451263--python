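"""Interference-EMG preprocessing and time-domain (TD) features.

The classic myocontrol feature set: per window and channel, root mean
square (RMS), slope sign changes (SSC), zero crossings (ZC) and waveform
length (WL), computed on 20-500 Hz zero-phase band-pass filtered EMG,
windowed at 100 ms with a 90 ms step, then reduced by PCA retaining 98% of
the variance. Features are z-scored with training-set statistics before
PCA (the four features live on heterogeneous scales).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError
from .types import EMGRecording, FeatureMatrix


@dataclass
class WindowSpec:
    """Sliding-window schedule in seconds; samples derive from the rate."""

    window_length: float = 0.100
    step: float = 0.090

    def window_samples(self, fs: float) -> int:
        n = round(self.window_length * fs)
        if n < 2:
            raise InvalidConfigError("window shorter than 2 samples")
        return n

    def step_samples(self, fs: float) -> int:
        n = round(self.step * fs)
        if n < 1:
            raise InvalidConfigError("step shorter than 1 sample")
        return n


@dataclass
class TDFeatureConfig:
    """Thresholds and filter settings for TD feature extraction.

    ``zc_threshold`` / ``ssc_threshold`` may be scalars or per-channel
    arrays (indexed by recording channel). SSC thresholds are in squared
    signal units.
    """

    zc_threshold: float | np.ndarray = 0.0
    ssc_threshold: float | np.ndarray = 0.0
    band: tuple[float, float] = (20.0, 500.0)
    filter_order: int = 5
    zero_phase: bool = True


# ---------------------------------------------------------------------------
# preprocessing


def bandpass(emg: EMGRecording, config: TDFeatureConfig | None = None) -> EMGRecording:
    """Zero-phase Butterworth band-pass (forward-backward 5th-order)."""
    config = config or TDFeatureConfig()
    low, high = config.band
    if not 0 < low < high:
        raise InvalidConfigError("band edges must satisfy 0 < low < high")
    if high >= emg.sample_rate / 2:
        raise InvalidConfigError(
            f"upper cutoff {high} Hz must be below Nyquist ({emg.sample_rate / 2} Hz)"
        )
    sos = sps.butter(config.filter_order, [low, high], btype="bandpass", fs=emg.sample_rate, output="sos")
    if config.zero_phase:
        filtered = sps.sosfiltfilt(sos, emg.samples, axis=1)
    else:
        filtered = sps.sosfilt(sos, emg.samples, axis=1)
    return emg.with_samples(filtered.astype(np.float32))


def exclude_channels(emg: EMGRecording, factor: float = 5.0) -> EMGRecording:
    """Mask channels whose RMS deviates from the median channel RMS.

    A channel is excluded when its RMS exceeds ``factor`` times the median
    RMS or falls below median/``factor`` (automated surrogate for the
    visual noisy-channel screening).
    """
    if factor < 1:
        raise InvalidConfigError("exclusion factor must be >= 1")
    rms_ch = np.sqrt(np.mean(emg.samples.astype(np.float64) ** 2, axis=1))
    med = np.median(rms_ch[~emg.bad_channel_mask])
    bad = emg.bad_channel_mask | (rms_ch > factor * med) | (rms_ch < med / factor)
    if bad.all():
        raise DegenerateInputError("all channels would be excluded")
    out = emg.with_samples(emg.samples)
    out.bad_channel_mask = bad
    return out


def segment(n_samples: int, spec: WindowSpec, fs: float) -> np.ndarray:
    """Half-open (start, end) sample intervals of the sliding windows.

    count = floor((n_samples - window)/step) + 1; a trailing partial
    window is discarded; fewer samples than one window yields an empty
    schedule.
    """
    w = spec.window_samples(fs)
    s = spec.step_samples(fs)
    if n_samples < w:
        return np.zeros((0, 2), dtype=np.int64)
    count = (n_samples - w) // s + 1
    starts = np.arange(count, dtype=np.int64) * s
    return np.stack([starts, starts + w], axis=1)


# ---------------------------------------------------------------------------
# scalar features (single window)


def rms(window: np.ndarray) -> float:
    """Root mean square of one window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise InvalidInputError("empty window")
    return float(np.sqrt(np.mean(window**2)))


def zero_crossings(window: np.ndarray, threshold: float = 0.0) -> int:
    """Sign changes between consecutive samples exceeding a jump threshold."""
    if threshold < 0:
        raise InvalidInputError("threshold must be nonnegative")
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        return 0
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero((a * b < 0) & (np.abs(a - b) >= threshold)))


def slope_sign_changes(window: np.ndarray, threshold: float = 0.0) -> int:
    """Local extrema count: (x_k - x_{k-1})(x_k - x_{k+1}) >= threshold."""
    if threshold < 0:
        raise InvalidInputError("threshold must be nonnegative")
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise InvalidInputError("slope sign changes need at least 3 samples")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return int(np.count_nonzero(left * right >= threshold))


def waveform_length(window: np.ndarray) -> float:
    """Cumulative absolute sample-to-sample variation."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise InvalidInputError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


# ---------------------------------------------------------------------------
# windowed extraction


def _channel_features(
    x: np.ndarray, intervals: np.ndarray, zc_thr: float, ssc_thr: float
) -> np.ndarray:
    """(n_windows, 4) RMS/SSC/ZC/WL for one channel, vectorized."""
    w = int(intervals[0, 1] - intervals[0, 0])
    starts = intervals[:, 0]
    step = int(starts[1] - starts[0]) if starts.size > 1 else 1
    usable = x[: starts[-1] + w]
    view = sliding_window_view(usable, w)[::step][: starts.size]
    out = np.empty((starts.size, 4))
    out[:, 0] = np.sqrt(np.mean(view**2, axis=1))
    left = view[:, 1:-1] - view[:, :-2]
    right = view[:, 1:-1] - view[:, 2:]
    out[:, 1] = np.count_nonzero(left * right >= ssc_thr, axis=1)
    a, b = view[:, :-1], view[:, 1:]
    out[:, 2] = np.count_nonzero((a * b < 0) & (np.abs(a - b) >= zc_thr), axis=1)
    out[:, 3] = np.sum(np.abs(np.diff(view, axis=1)), axis=1)
    return out


def extract_td(
    emg: EMGRecording, spec: WindowSpec, config: TDFeatureConfig | None = None
) -> FeatureMatrix:
    """Windowed TD features across all active channels.

    Column order is channel-major: for each active channel the four
    features RMS, SSC, ZC, WL.
    """
    config = config or TDFeatureConfig()
    intervals = segment(emg.n_samples, spec, emg.sample_rate)
    channels = emg.active_channels
    if channels.size == 0:
        raise DegenerateInputError("no active channels")
    zc_thr = np.broadcast_to(np.asarray(config.zc_threshold, dtype=float), (emg.n_channels,))
    ssc_thr = np.broadcast_to(np.asarray(config.ssc_threshold, dtype=float), (emg.n_channels,))
    blocks = []
    labels = []
    x64 = emg.samples.astype(np.float64)
    for ch in channels:
        blocks.append(_channel_features(x64[ch], intervals, zc_thr[ch], ssc_thr[ch]))
        labels += [f"ch{ch:02d}_{name}" for name in ("rms", "ssc", "zc", "wl")]
    values = (
        np.concatenate(blocks, axis=1) if intervals.size else np.zeros((0, 4 * channels.size))
    )
    return FeatureMatrix(values=values, window_end_sample=intervals[:, 1], labels=labels)


def rest_noise_thresholds(
    emg: EMGRecording, rest_mask: np.ndarray, full_scale: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel ZC/SSC thresholds from rest-period noise.

    zc = 3 * 1.4826 * MAD of the rest signal, clipped to at most 10% of
    full scale (the manual visual-inspection choice is replaced by a
    robust noise estimate); ssc = zc**2 (squared-signal units).
    """
    rest_mask = np.asarray(rest_mask, dtype=bool)
    if rest_mask.shape != (emg.n_samples,):
        raise InvalidInputError("rest mask length must equal n_samples")
    if not rest_mask.any():
        raise InvalidInputError("no rest samples available for threshold estimation")
    rest = emg.samples[:, rest_mask].astype(np.float64)
    mad = np.median(np.abs(rest - np.median(rest, axis=1, keepdims=True)), axis=1)
    zc = 3.0 * 1.4826 * mad
    if full_scale is None:
        full_scale = float(np.max(np.abs(emg.samples))) or 1.0
    zc = np.minimum(zc, 0.1 * full_scale)
    return zc, zc**2


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCABasis:
    """Standardization + principal-component projection fit on training data."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (retained, n_features) orthonormal rows
    explained_variance_ratio: np.ndarray  # all components
    retained: int
    target_variance: float


def fit_pca(train: FeatureMatrix | np.ndarray, variance: float = 0.98) -> PCABasis:
    """Smallest component count whose cumulative explained variance >= target.

    Features are z-scored with training statistics first; constant columns
    get unit scale (they carry no variance).
    """
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("PCA needs at least 2 training rows")
    if not 0 < variance <= 1:
        raise InvalidConfigError("variance target must be in (0, 1]")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise DegenerateInputError("constant feature matrix: nothing to retain")
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    retained = int(np.searchsorted(cumulative, variance - 1e-12) + 1)
    retained = min(retained, evr.size)
    return PCABasis(
        mean=mean,
        scale=scale,
        components=pca.components_[:retained],
        explained_variance_ratio=evr,
        retained=retained,
        target_variance=variance,
    )


def apply_pca(basis: PCABasis, matrix: FeatureMatrix) -> FeatureMatrix:
    """Project features through a fitted basis (training stats unchanged)."""
    if matrix.n_features != basis.mean.size:
        raise InvalidInputError("feature dimension does not match PCA basis")
    Z = (matrix.values - basis.mean) / basis.scale
    proj = Z @ basis.components.T
    labels = [f"pc{j + 1}" for j in range(basis.retained)]
    return FeatureMatrix(
        values=proj, window_end_sample=matrix.window_end_sample, labels=labels
    )
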