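"""ERP analysis: band-pass, epoching, baseline correction, grand average.

For visualizing the readiness potential, the continuous recording is
band-pass filtered to 0.1-4 Hz (4th-order Butterworth, zero-phase), cut
into epochs from -1.5 s to 0 s around each movement onset, and
baseline-corrected on [-1.5, -1] s.  Epochs are averaged per task and
pooled across subjects into a grand average.  An optional peak-to-peak
amplitude rejection replaces artifact screening; the synthetic generator
produces no blinks, so it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

EPOCH_SPAN_S = (-1.5, 0.0)
BASELINE_SPAN_S = (-1.5, -1.0)
DEFAULT_BAND_HZ = (0.1, 4.0)


def epoch_baseline(recording, onsets, band=DEFAULT_BAND_HZ,
                   reject_ptp: float | None = None) -> np.ndarray:
    """Band-passed, baseline-corrected epochs around movement onsets.

    Returns (n_epochs, channels, 750) for the [-1.5, 0) s span at 500 Hz;
    per-channel means over the [-1.5, -1] s baseline are subtracted.
    Onsets without 1.5 s of history (or beyond the recording) are skipped;
    with ``reject_ptp`` set, epochs whose peak-to-peak amplitude exceeds
    it (microvolts) are dropped.
    """
    rate = recording.rate
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(recording.samples,
                                                  dtype=np.float64), axis=1)
    n_span = int(round((EPOCH_SPAN_S[1] - EPOCH_SPAN_S[0]) * rate))
    n_base = int(round((BASELINE_SPAN_S[1] - BASELINE_SPAN_S[0]) * rate))
    epochs = []
    for onset in np.atleast_1d(onsets):
        i1 = int(round(onset * rate))
        i0 = i1 - n_span
        if i0 < 0 or i1 > filtered.shape[1]:
            continue
        ep = filtered[:, i0:i1].copy()
        ep -= ep[:, :n_base].mean(axis=1, keepdims=True)
        if reject_ptp is not None and np.ptp(ep, axis=1).max() > reject_ptp:
            continue
        epochs.append(ep)
    if not epochs:
        return np.empty((0, filtered.shape[0], n_span))
    return np.stack(epochs)


@dataclass
class GrandAverage:
    """Mean ERP over all pooled epochs of a task."""

    mean: np.ndarray     # channels x time
    n_epochs: int
    rate: float = 500.0

    def times(self) -> np.ndarray:
        n = self.mean.shape[1]
        return EPOCH_SPAN_S[0] + np.arange(n) / self.rate


def grand_average(epochs, rate: float = 500.0) -> GrandAverage:
    """Arithmetic mean over epochs, pooled across subjects.

    ``epochs`` is either one (n, channels, time) array or an iterable of
    such chunks (e.g. one per subject), which are pooled with per-chunk
    weights equal to their epoch counts.
    """
    if isinstance(epochs, np.ndarray):
        chunks = [epochs]
    else:
        chunks = [np.asarray(e) for e in epochs]
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        raise ValueError("no epochs to average")
    total = sum(len(c) for c in chunks)
    acc = np.zeros(chunks[0].shape[1:], dtype=np.float64)
    for c in chunks:
        acc += c.sum(axis=0)
    return GrandAverage(mean=acc / total, n_epochs=total, rate=rate)
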