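"""Sliding-window grid and window-to-feature transform.

Each trial contributes 81 overlapping 1 s windows, stepping 0.05 s from
[-5.00, -4.00] s to [-1.00, 0.00] s relative to the labeled movement
onset.  Every window is transformed independently:

1. channel-wise standardization using the window's own mean/SD,
2. decimation 500 Hz -> 20 Hz fused with an FFT bandpass keeping
   0.1-4.0 Hz (bins 1-4 Hz of the 1 s window; DC removed),
4. xDAWN spatial filtering to 4 pseudo-channels (filters fitted on
   training windows only),
5. the last 4 samples (0.2 s) of each pseudo-channel, flattened
   channel-major, giving 16 time-domain features,
6. Gaussian feature normalization with training-set statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

WINDOW_LENGTH_S = 1.0
WINDOW_STEP_S = 0.05
GRID_START_S = -5.0
GRID_END_S = -1.0
TARGET_RATE_HZ = 20.0
BAND_LOW_HZ = 0.1
BAND_HIGH_HZ = 4.0
N_PSEUDO_CHANNELS = 4
N_FEATURE_SAMPLES = 4


@dataclass(frozen=True)
class WindowGrid:
    """The 81-window sliding grid relative to the movement onset."""

    window_length: float = WINDOW_LENGTH_S
    step: float = WINDOW_STEP_S
    first_start: float = GRID_START_S
    last_start: float = GRID_END_S

    @property
    def starts(self) -> np.ndarray:
        n = int(round((self.last_start - self.first_start) / self.step)) + 1
        return self.first_start + self.step * np.arange(n)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def windows(self) -> list:
        return [(s, s + self.window_length) for s in self.starts]

    def index_of(self, start: float) -> int:
        idx = int(round((start - self.first_start) / self.step))
        if not 0 <= idx < self.n_windows or \
                abs(self.starts[idx] - start) > 1e-9:
            raise ValueError(f"window start {start} not on the grid")
        return idx


DEFAULT_GRID = WindowGrid()


class InsufficientHistoryError(ValueError):
    """Trial onset has less pre-onset data than the grid requires."""


def cut_windows(recording, onset: float,
                grid: WindowGrid = DEFAULT_GRID) -> np.ndarray:
    """Cut the trial's sliding windows from a continuous recording.

    Returns an array (n_windows, channels, window samples); extraction uses
    half-open sample ranges [start, start + 1 s) on the recording's grid.
    """
    rate = recording.rate
    n_win_samples = int(round(grid.window_length * rate))
    first = onset + grid.first_start
    if first < 0 or onset > recording.duration:
        raise InsufficientHistoryError(
            f"onset {onset:.2f} s needs {-grid.first_start:.0f} s of "
            f"history inside the recording")
    starts = np.round((onset + grid.starts) * rate).astype(int)
    out = np.empty((grid.n_windows, recording.samples.shape[0],
                    n_win_samples), dtype=np.float64)
    for i, s in enumerate(starts):
        out[i] = recording.samples[:, s:s + n_win_samples]
    return out


def preprocess_window(windows: np.ndarray,
                      rate: float = 500.0) -> np.ndarray:
    """Standardize, decimate to 20 Hz, and FFT-bandpass one or more windows.

    ``windows`` is (..., channels, samples) at ``rate``; the result is
    (..., channels, 20).  Standardization uses each window's own per-channel
    mean and SD (zero-variance channels map to all-zeros).  Decimation and
    the bandpass are performed as one exact operation in the frequency
    domain: the real-FFT bins of the full-rate window with center frequency
    in [0.1, 4.0] Hz — the 1-4 Hz bins of the 1 s window, DC removed — are
    retained and inverse-transformed at the 20 Hz target rate.  Because the
    passband lies far below the target Nyquist (10 Hz), the band selection
    itself anti-aliases; out-of-band tones leave no edge transients, unlike
    a time-domain anti-aliasing filter.
    """
    x = np.asarray(windows, dtype=np.float64)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    x = (x - mean) / sd_safe
    x = np.where(sd == 0, 0.0, x)
    n_in = x.shape[-1]
    n_out = int(round(n_in * TARGET_RATE_HZ / rate))
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n_in, d=1.0 / rate)
    keep = (f >= BAND_LOW_HZ) & (f <= BAND_HIGH_HZ)
    spec[..., ~keep] = 0.0
    # spectral truncation to the target bins; scale preserves amplitude
    spec = spec[..., :n_out // 2 + 1] * (n_out / n_in)
    return np.fft.irfft(spec, n=n_out, axis=-1)


@dataclass
class XdawnFilter:
    """xDAWN spatial filters enhancing the evoked LRP response.

    ``weights`` is (input channels x n_filters); pseudo-channels are
    ordered by decreasing generalized eigenvalue (evoked-response energy
    over total signal energy).  ``fold_tag`` records which training fold
    fitted the filter, for train/test hygiene checks.
    """

    weights: np.ndarray
    eigenvalues: np.ndarray
    classes: tuple = ("NoLRP", "LRP")
    fold_tag: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("xDAWN weights must be finite")

    @property
    def n_filters(self) -> int:
        return self.weights.shape[1]


def fit_xdawn(windows: np.ndarray, labels: np.ndarray,
              n_filters: int = N_PSEUDO_CHANNELS,
              ridge: float = 1e-8, fold_tag: str = "") -> XdawnFilter:
    """Fit xDAWN filters on labeled training windows.

    ``windows`` is (n, channels, time) of preprocessed windows; ``labels``
    is boolean/int with 1 = LRP.  Solves the generalized eigenproblem
    maximizing the evoked (LRP-average) response energy against the pooled
    signal energy of all windows; the top ``n_filters`` eigenvectors are
    returned in decreasing-eigenvalue order.  Near-singular pooled
    covariance is ridge-regularized by ``ridge * trace / dim``.
    """
    x = np.asarray(windows, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if x.ndim != 3:
        raise ValueError("windows must be (n, channels, time)")
    n_channels = x.shape[1]
    if n_channels < n_filters:
        raise ValueError(f"need at least {n_filters} channels")
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present to fit xDAWN")
    t = x.shape[2]
    evoked = x[y].mean(axis=0)
    s_cov = evoked @ evoked.T / t
    n_cov = np.einsum("ict,idt->cd", x, x) / (x.shape[0] * t)
    reg = ridge * np.trace(n_cov) / n_channels
    n_cov = n_cov + reg * np.eye(n_channels)
    vals, vecs = linalg.eigh(s_cov, n_cov)
    order = np.argsort(vals)[::-1][:n_filters]
    return XdawnFilter(weights=vecs[:, order], eigenvalues=vals[order],
                       fold_tag=fold_tag)


def apply_xdawn(windows: np.ndarray, filt: XdawnFilter) -> np.ndarray:
    """Project windows onto the xDAWN pseudo-channels (linear, stateless)."""
    x = np.asarray(windows, dtype=np.float64)
    if x.shape[-2] != filt.weights.shape[0]:
        raise ValueError(
            f"window channel count {x.shape[-2]} does not match filter "
            f"rows {filt.weights.shape[0]}")
    return np.einsum("cf,...ct->...ft", filt.weights, x)


@dataclass
class FeatureNormalizer:
    """Gaussian (z-score) feature normalization with training statistics.

    Zero-SD features are mapped with SD := 1 and flagged via a warning at
    fit time.
    """

    mean: np.ndarray
    sd: np.ndarray
    fold_tag: str = ""

    @classmethod
    def fit(cls, features: np.ndarray,
            fold_tag: str = "") -> "FeatureNormalizer":
        f = np.asarray(features, dtype=np.float64)
        mean = f.mean(axis=0)
        sd = f.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("zero-variance features mapped with SD := 1",
                          RuntimeWarning, stacklevel=2)
            sd = np.where(sd == 0, 1.0, sd)
        return cls(mean=mean, sd=sd, fold_tag=fold_tag)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=np.float64) - self.mean) / self.sd


def extract_features(windows: np.ndarray,
                     normalizer: FeatureNormalizer | None = None,
                     n_samples: int = N_FEATURE_SAMPLES) -> np.ndarray:
    """Last-0.2 s time-domain features of pseudo-channel windows.

    ``windows`` is (..., pseudo-channels, time); the last ``n_samples``
    samples of each pseudo-channel are flattened channel-major into a
    16-value feature vector per window, optionally z-scored with training
    statistics.
    """
    x = np.asarray(windows, dtype=np.float64)
    feats = x[..., -n_samples:].reshape(*x.shape[:-2], -1)
    if normalizer is not None:
        feats = normalizer.transform(feats)
    return feats
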