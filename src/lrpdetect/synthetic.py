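"""Seeded synthetic study generator.

Emulates the self-paced reaching experiment end to end: for every subject
and task (unilateral right-arm / bilateral), a continuous 64-channel EEG
recording at 500 Hz with an event table (hand-switch press/release, button
press, invalid-trial markers), per-trial 3-D hand-marker trajectories, and
a ground-truth table of movement onsets.

The EEG is 1/f-shaped correlated Gaussian noise plus, for every trial, an
LRP-like slow negative ramp that peaks at the true movement onset.  The
ramp is injected with a lateralized spatial pattern: maximal at C1/C3 (left
motor cortex, contralateral to the moved right arm) for unilateral trials
and symmetric over C1/C2/C3/C4 for bilateral trials.  Reaches follow a
minimum-jerk trajectory of ~390 mm (30 cm forward, 25 cm up); the hand
switch releases a short mechanical delay after the true onset.

Everything is driven by :class:`~lrpdetect.config.StudyConfig` and a seed;
identical configurations produce bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft

from .config import ConfigError, StudyConfig, TASKS
from .montage import CHANNELS_64

EVENT_KINDS = ("switch_press", "switch_release", "button_press",
               "invalid_trial")

# Spatial weights of the injected LRP pattern, peak 1.0 at C1 (left motor
# cortex).  The bilateral pattern mirrors the left-hemisphere weights onto
# the right hemisphere, so C1 and C2 carry equal weight by construction.
_PATTERN_LEFT = {
    "C1": 1.0, "C3": 0.8, "FC1": 0.6, "CP1": 0.6, "FC3": 0.5, "CP3": 0.5,
    "C5": 0.3, "FC5": 0.25, "CP5": 0.25,
}
_PATTERN_MIDLINE = {"Cz": 0.4, "CPz": 0.3}
_PATTERN_RIGHT = {
    "C2": 1.0, "C4": 0.8, "FC2": 0.6, "CP2": 0.6, "FC4": 0.5, "CP4": 0.5,
    "C6": 0.3, "FC6": 0.25, "CP6": 0.25,
}


class GenerationError(ValueError):
    """Raised when a trial cannot be synthesized as requested."""


@dataclass
class EventTable:
    """Event stream of a recording: (time, kind, side) rows.

    ``kind`` is one of ``switch_press``, ``switch_release``,
    ``button_press``, ``invalid_trial``; ``side`` is ``left``/``right``/
    ``both``.  Times are seconds from recording start and non-decreasing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time", "kind", "side"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        bad = set(self.frame["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        t = self.frame["time"].to_numpy()
        if len(t) and np.any(np.diff(t) < 0):
            raise ValueError("event times must be non-decreasing")

    def of_kind(self, kind: str) -> np.ndarray:
        return self.frame.loc[self.frame["kind"] == kind, "time"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class Recording:
    """Continuous multichannel EEG with named channels and events.

    ``samples`` is channels x time in microvolts (float32); FCz is the
    recording reference and is not a data channel.
    """

    channel_names: tuple
    rate: float
    samples: np.ndarray
    events: EventTable

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("samples row count != number of channels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        t = self.events.frame["time"].to_numpy()
        if len(t) and (t.min() < 0 or t.max() > self.duration):
            raise ValueError("event times outside the recording")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate

    def select_channels(self, idx) -> "Recording":
        names = tuple(self.channel_names[i] for i in idx)
        return Recording(channel_names=names, rate=self.rate,
                         samples=self.samples[list(idx)], events=self.events)


@dataclass
class MotionTrace:
    """Per-trial 3-D marker positions (mm) of one hand.

    ``t_start`` anchors the trace on the recording clock; the trace spans
    the trial's rest period and the reach.  ``switch_release`` is the
    absolute time the mechanical hand switch opened.
    """

    positions: np.ndarray        # time x 3, mm
    rate: float
    t_start: float
    switch_release: float
    hand: str = "right"
    set_index: int = 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be a time x 3 array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("motion trace contains non-finite positions")
        if not (self.t_start <= self.switch_release <= self.t_end):
            raise ValueError("switch_release outside trial bounds")

    @property
    def t_end(self) -> float:
        return self.t_start + len(self.positions) / self.rate

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.positions)) / self.rate


@dataclass
class SubjectTaskData:
    """One subject-task cell: EEG recording, motion traces, ground truth."""

    subject: int
    task: str
    recording: Recording
    motion: list
    trials: pd.DataFrame   # set_index, trial_index, true_onset, rest, valid


def _rng(config: StudyConfig, *key: int) -> np.random.Generator:
    """Deterministic child stream keyed by (seed, *key)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *key]))


def _ramp(config: StudyConfig, rate: float) -> np.ndarray:
    """Temporal LRP template on the sample grid.

    Zero before ``-lrp_duration``, reaches 1 at 0 (the onset), decays back
    to zero over ``lrp_decay`` seconds.  Returned as the unit-amplitude
    envelope; multiply by ``lrp_amplitude`` for microvolts.
    """
    n_up = int(round(config.lrp_duration * rate))
    n_down = int(round(config.lrp_decay * rate))
    x = np.arange(n_up + 1) / n_up
    if config.ramp_shape == "half_cosine":
        up = 0.5 * (1.0 - np.cos(np.pi * x))
    else:
        up = x
    down = 1.0 - np.arange(1, n_down + 1) / max(n_down, 1)
    return np.concatenate([up, down])


def spatial_pattern(task: str, channel_names) -> np.ndarray:
    """Per-channel weights of the injected LRP pattern (peak 1.0 at C1)."""
    if task not in TASKS:
        raise ConfigError(f"task must be one of {TASKS}, got {task!r}")
    weights = dict(_PATTERN_LEFT)
    weights.update(_PATTERN_MIDLINE)
    if task == "bilateral":
        weights.update(_PATTERN_RIGHT)
    return np.array([weights.get(c, 0.0) for c in channel_names])


def _make_noise(config: StudyConfig, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    """Correlated 1/f-shaped Gaussian noise, channels x time, microvolts.

    Equicorrelated white noise (shared component with weight sqrt(rho)) is
    spectrally shaped to power ~ 1/f^exponent and rescaled per channel to
    ``noise_sd`` microvolts.
    """
    c = config.n_channels
    rho = config.noise_correlation
    # single precision throughout: ample for noise, and long recordings
    # make the elementwise and FFT work memory-bound
    w = rng.standard_normal((c, n_samples), dtype=np.float32)
    if rho > 0:
        shared = rng.standard_normal(n_samples, dtype=np.float32)
        w *= np.float32(np.sqrt(1.0 - rho))
        w += np.float32(np.sqrt(rho)) * shared
    if config.noise_sd == 0:
        return np.zeros((c, n_samples), dtype=np.float32)
    if not config.white_noise:
        # pad to an FFT-friendly length; awkward sample counts otherwise
        # hit the slow Bluestein path
        n_fast = fft.next_fast_len(n_samples, real=True)
        spec = np.fft.rfft(w, n=n_fast, axis=1)
        f = np.fft.rfftfreq(n_fast, d=1.0 / config.eeg_rate)
        shape = np.zeros_like(f, dtype=np.float32)
        shape[1:] = f[1:] ** (-config.noise_exponent / 2.0)
        spec *= shape
        w = np.fft.irfft(spec, n=n_fast, axis=1)[:, :n_samples]
        w = np.ascontiguousarray(w, dtype=np.float32)
    sd = w.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    w *= (np.float32(config.noise_sd) / sd)
    return w


def _inject_lrp(samples: np.ndarray, config: StudyConfig, task: str,
                onsets, rate: float) -> None:
    """Add the LRP template (pattern x ramp x amplitude) at each onset."""
    channels = CHANNELS_64[:config.n_channels]
    pattern = spatial_pattern(task, channels) * config.lrp_amplitude
    ramp = _ramp(config, rate)
    n = samples.shape[1]
    for onset in onsets:
        i0 = int(round((onset - config.lrp_duration) * rate))
        i1 = i0 + len(ramp)
        lo, hi = max(i0, 0), min(i1, n)
        if hi <= lo:
            continue
        seg = ramp[lo - i0:hi - i0]
        samples[:, lo:hi] += (pattern[:, None] * seg[None, :]).astype(
            samples.dtype)


def synthesize_trial_eeg(config: StudyConfig, task: str, true_onset: float,
                         rng: np.random.Generator,
                         duration: float | None = None) -> np.ndarray:
    """One trial's EEG segment: noise plus the lateralized LRP template.

    The returned array is channels x time (microvolts).  ``true_onset`` is
    seconds from segment start and must leave at least
    ``rest_duration_min`` seconds of pre-onset data.
    """
    if true_onset < config.rest_duration_min:
        raise GenerationError(
            f"true_onset={true_onset} leaves less than "
            f"{config.rest_duration_min} s of pre-onset rest")
    if duration is None:
        duration = true_onset + config.reach_duration + 1.0
    if duration <= true_onset:
        raise GenerationError("duration must exceed true_onset")
    n = int(round(duration * config.eeg_rate))
    samples = _make_noise(config, n, rng)
    _inject_lrp(samples, config, task, [true_onset], config.eeg_rate)
    return samples


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def synthesize_trial_motion(config: StudyConfig, true_onset: float,
                            rng: np.random.Generator,
                            t_start: float = 0.0,
                            t_end: float | None = None,
                            hand: str = "right",
                            set_index: int = 0,
                            trial_index: int = 0) -> MotionTrace:
    """Minimum-jerk reach trajectory with rest jitter and switch release.

    The marker rests near the origin (jitter ``motion_jitter_sd`` mm SD),
    then displaces by ``reach_target`` (default 30 cm forward, 25 cm up,
    ~390.5 mm total) over ``reach_duration`` seconds starting at
    ``true_onset``.  The mechanical switch releases ``switch_delay``
    seconds after the true onset.
    """
    if t_end is None:
        t_end = true_onset + config.reach_duration + 0.5
    if not (t_start < true_onset < t_end):
        raise GenerationError("true_onset outside trace bounds")
    n = int(round((t_end - t_start) * config.motion_rate))
    t = t_start + np.arange(n) / config.motion_rate
    tau = (t - true_onset) / config.reach_duration
    target = np.asarray(config.reach_target, dtype=float)
    pos = _minimum_jerk(tau)[:, None] * target[None, :]
    if config.motion_jitter_sd > 0:
        pos = pos + rng.normal(0.0, config.motion_jitter_sd, size=(n, 3))
    return MotionTrace(positions=pos, rate=config.motion_rate,
                       t_start=t_start,
                       switch_release=true_onset + config.switch_delay,
                       hand=hand, set_index=set_index,
                       trial_index=trial_index)


def _pack_trials(config: StudyConfig, rng: np.random.Generator):
    """Lay out the self-paced trials of one subject-task on the clock.

    Each trial: hands at rest on the switches (switch press), a rest period
    drawn uniformly from [rest_min, rest_max] (or, with probability
    ``invalid_fraction``, a too-short rest in [3.5, 5) s flagged invalid),
    the true movement onset, switch release after the mechanical delay, the
    button press at the end of the reach, then the return to the switches.
    """
    rows = []
    sp = 1.0  # first switch press; 1 s of settled signal before it
    n_sets, n_trials = config.n_sets_per_task, config.n_trials_per_set
    for s in range(n_sets):
        for k in range(n_trials):
            invalid = rng.random() < config.invalid_fraction
            if invalid:
                rest = rng.uniform(3.5, 5.0)
            else:
                rest = rng.uniform(config.rest_duration_min,
                                   config.rest_duration_max)
            onset = sp + rest
            rows.append(dict(set_index=s, trial_index=k, switch_press=sp,
                             rest=rest, true_onset=onset,
                             switch_release=onset + config.switch_delay,
                             button_press=onset + config.reach_duration,
                             valid=not invalid))
            sp = onset + config.reach_duration + config.return_duration
    return pd.DataFrame(rows)


def _build_events(plan: pd.DataFrame, side: str) -> EventTable:
    rows = []
    for r in plan.itertuples():
        rows.append((r.switch_press, "switch_press", side))
        if not r.valid:
            rows.append((r.true_onset, "invalid_trial", side))
        rows.append((r.switch_release, "switch_release", side))
        rows.append((r.button_press, "button_press", side))
    frame = pd.DataFrame(rows, columns=["time", "kind", "side"])
    return EventTable(frame.sort_values("time", kind="stable",
                                        ignore_index=True))


def _generate_subject_task(config: StudyConfig, subject: int,
                           task: str) -> SubjectTaskData:
    task_idx = TASKS.index(task)
    plan = _pack_trials(config, _rng(config, subject, task_idx, 0))
    duration = float(plan["button_press"].iloc[-1]) \
        + config.return_duration + 1.0
    n = int(round(duration * config.eeg_rate))
    samples = _make_noise(config, n, _rng(config, subject, task_idx, 1))
    _inject_lrp(samples, config, task, plan["true_onset"].to_numpy(),
                config.eeg_rate)
    side = "right" if task == "unilateral" else "both"
    recording = Recording(channel_names=CHANNELS_64[:config.n_channels],
                          rate=config.eeg_rate, samples=samples,
                          events=_build_events(plan, side))
    hands = ("right",) if task == "unilateral" else ("left", "right")
    motion = []
    m_rng = _rng(config, subject, task_idx, 2)
    for r in plan.itertuples():
        for hand in hands:
            motion.append(synthesize_trial_motion(
                config, r.true_onset, m_rng, t_start=r.switch_press,
                t_end=r.button_press + 0.5, hand=hand,
                set_index=r.set_index, trial_index=r.trial_index))
    trials = plan[["set_index", "trial_index", "true_onset", "rest",
                   "valid"]].copy()
    trials["task"] = task
    return SubjectTaskData(subject=subject, task=task, recording=recording,
                           motion=motion, trials=trials)


class StudyDataset:
    """Lazily generated synthetic study: all subjects, both tasks.

    Subject-task cells are generated on demand from independent seeded
    streams (a small cache bounds memory for full-size studies); repeated
    access and repeated construction with the same config are
    deterministic.
    """

    def __init__(self, config: StudyConfig, cache_size: int = 2):
        self.config = config
        self._cache: dict = {}
        self._cache_size = cache_size

    @property
    def tasks(self) -> tuple:
        return TASKS

    @property
    def subjects(self) -> range:
        return range(self.config.n_subjects)

    def subject_task(self, subject: int, task: str) -> SubjectTaskData:
        if not 0 <= subject < self.config.n_subjects:
            raise ConfigError(f"subject {subject} out of range")
        if task not in TASKS:
            raise ConfigError(f"task must be one of {TASKS}, got {task!r}")
        key = (subject, task)
        if key not in self._cache:
            if len(self._cache) >= self._cache_size:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = _generate_subject_task(self.config, subject,
                                                      task)
        return self._cache[key]

    def __iter__(self):
        for subject in self.subjects:
            for task in TASKS:
                yield self.subject_task(subject, task)


def generate_dataset(config: StudyConfig) -> StudyDataset:
    """Generate the full synthetic study for ``config`` (lazily)."""
    return StudyDataset(config)
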