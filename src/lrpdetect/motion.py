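"""Physical movement-onset estimation from motion-capture kinematics.

The ground-truth onset of each self-paced reach is estimated from the hand
marker trajectory: positions are re-zeroed to the resting position (mean
over the first second of the trial), the Euclidean distance to rest and
its first difference (low-pass filtered, per-trial max-normalized
velocity) are combined by multiplication, and the onset is found by
scanning backward in time from the mechanical switch release for the
latest sample whose distance-velocity product falls below a 0.6 mm
threshold.  The product is insensitive both to small position fluctuations
(which produce spurious velocity) and to slight shifts of the resting
position between trials.

For bilateral trials the left-hand trace provides the onset, mirroring the
intended use where the unimpaired arm labels the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import MotionTrace, SubjectTaskData

DEFAULT_THRESHOLD_MM = 0.6
VELOCITY_CUTOFF_HZ = 4.0
VELOCITY_FILTER_ORDER = 4


class OnsetNotFoundError(RuntimeError):
    """No sample below threshold before the switch release."""


class DegenerateTrialError(RuntimeError):
    """The trace shows no movement at all (zero velocity throughout)."""


@dataclass
class KinematicProfile:
    """Distance / normalized-velocity / product series of one trial."""

    distance: np.ndarray      # mm, Euclidean distance to rest
    velocity: np.ndarray      # dimensionless, per-trial max of 1
    product: np.ndarray       # mm, distance * velocity
    rate: float
    t_start: float

    def time_to_index(self, t: float) -> int:
        idx = int(round((t - self.t_start) * self.rate))
        if not 0 <= idx < len(self.product):
            raise ValueError(f"time {t} s outside the profile")
        return idx


@dataclass
class OnsetEstimate:
    onset_time: float          # seconds, recording clock
    method_threshold: float    # mm
    search_start: float        # switch release time

    def __post_init__(self) -> None:
        if self.onset_time > self.search_start:
            raise ValueError("onset cannot be after the search start")


def kinematic_profile(trace: MotionTrace, rest_window: float = 1.0,
                      zero_phase: bool = True) -> KinematicProfile:
    """Distance, filtered normalized velocity, and their product.

    Positions are re-zeroed by subtracting the mean over the first
    ``rest_window`` seconds; velocity is the one-sample forward difference
    of the distance series (first sample 0), low-pass filtered at 4 Hz
    (4th-order Butterworth, zero-phase by default to avoid onset bias) and
    normalized to the trial's maximum.
    """
    n_rest = int(round(rest_window * trace.rate))
    if len(trace.positions) <= n_rest:
        raise ValueError("trace shorter than the rest window")
    pos = trace.positions - trace.positions[:n_rest].mean(axis=0)
    distance = np.linalg.norm(pos, axis=1)
    velocity = np.diff(distance, prepend=distance[0])
    sos = signal.butter(VELOCITY_FILTER_ORDER, VELOCITY_CUTOFF_HZ,
                        btype="low", fs=trace.rate, output="sos")
    if zero_phase:
        velocity = signal.sosfiltfilt(sos, velocity)
    else:
        velocity = signal.sosfilt(sos, velocity)
    vmax = np.max(np.abs(velocity))
    if vmax == 0:
        raise DegenerateTrialError("no movement in trace (zero velocity)")
    velocity = velocity / vmax
    return KinematicProfile(distance=distance, velocity=velocity,
                            product=distance * velocity, rate=trace.rate,
                            t_start=trace.t_start)


def estimate_onset(profile: KinematicProfile, switch_release: float,
                   threshold: float = DEFAULT_THRESHOLD_MM) -> OnsetEstimate:
    """Backward threshold search for the movement onset.

    Scanning backward in time from the switch release, the onset is the
    latest sample whose product magnitude is below ``threshold`` mm.
    """
    start = profile.time_to_index(switch_release)
    below = np.abs(profile.product[:start + 1]) < threshold
    if not below.any():
        raise OnsetNotFoundError(
            "no sample below threshold before switch release")
    idx = np.nonzero(below)[0][-1]
    # the rounded sample time may exceed the release by < half a sample
    onset_time = min(profile.t_start + idx / profile.rate, switch_release)
    return OnsetEstimate(onset_time=onset_time,
                         method_threshold=threshold,
                         search_start=switch_release)


def label_hand(task: str) -> str:
    """Which hand's trace provides the onset label for a task."""
    return "left" if task == "bilateral" else "right"


def annotate_dataset(data: SubjectTaskData,
                     threshold: float = DEFAULT_THRESHOLD_MM,
                     rest_window: float = 1.0) -> pd.DataFrame:
    """Estimate one onset marker per valid trial of a subject-task cell.

    Uses the left-hand trace for bilateral trials and the right-hand trace
    for unilateral ones.  Trials flagged invalid (rest under 5 s) and
    trials whose backward search fails are excluded.  Returns a table with
    columns ``set_index, trial_index, onset, true_onset`` sorted by trial.
    """
    hand = label_hand(data.task)
    traces = {(m.set_index, m.trial_index): m
              for m in data.motion if m.hand == hand}
    valid = data.trials[data.trials["valid"]]
    missing = [key for key in zip(valid["set_index"], valid["trial_index"])
               if key not in traces]
    if missing:
        raise ValueError(
            f"motion traces missing for valid trials: {missing[:5]}")
    rows = []
    for r in valid.itertuples():
        trace = traces[(r.set_index, r.trial_index)]
        try:
            profile = kinematic_profile(trace, rest_window=rest_window)
            est = estimate_onset(profile, trace.switch_release,
                                 threshold=threshold)
        except (OnsetNotFoundError, DegenerateTrialError):
            continue
        rows.append(dict(set_index=r.set_index, trial_index=r.trial_index,
                         onset=est.onset_time, true_onset=r.true_onset))
    return pd.DataFrame(rows,
                        columns=["set_index", "trial_index", "onset",
                                 "true_onset"])
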