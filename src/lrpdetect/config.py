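"""Study configuration for the synthetic experiment generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the emulated reaching study.

    Defaults reproduce the study design: 8 subjects, two tasks (unilateral
    right-arm and bilateral reaches), 3 sets of 40 self-paced trials each,
    64-channel EEG at 500 Hz with at least 5 s of rest before every
    movement.  The LRP is injected as a slow negative ramp (peak
    ``lrp_amplitude`` microvolts at movement onset) with a lateralized
    spatial pattern, on top of 1/f-shaped background noise.
    """

    n_subjects: int = 8
    n_sets_per_task: int = 3
    n_trials_per_set: int = 40
    eeg_rate: float = 500.0
    motion_rate: float = 500.0
    n_channels: int = 64
    rest_duration_min: float = 5.0
    rest_duration_max: float = 7.0
    lrp_amplitude: float = -6.0      # microvolts at the ramp peak (negative)
    lrp_duration: float = 1.0        # seconds of pre-onset ramp
    lrp_decay: float = 0.3           # seconds of post-onset decay back to 0
    noise_sd: float = 10.0           # microvolts per channel
    noise_exponent: float = 1.0      # spectral exponent of the 1/f noise
    noise_correlation: float = 0.2   # inter-channel noise correlation
    white_noise: bool = False        # flat spectrum instead of 1/f
    ramp_shape: str = "linear"       # "linear" or "half_cosine"
    invalid_fraction: float = 0.0    # fraction of trials with rest < 5 s
    reach_duration: float = 0.8      # seconds from onset to button press
    reach_target: tuple = (0.0, 300.0, 250.0)  # mm displacement of the reach
    return_duration: float = 1.2     # seconds from button back to the switch
    motion_jitter_sd: float = 0.2    # mm of marker jitter at rest
    switch_delay: float = 0.015      # s between true onset and switch release
    lead_in: float = 6.0             # s of rest at the start of a recording
    seed: int = 0

    def __post_init__(self) -> None:
        counts = ("n_subjects", "n_sets_per_task", "n_trials_per_set",
                  "n_channels")
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("eeg_rate", "motion_rate", "lrp_duration",
                     "reach_duration", "return_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.rest_duration_min < 5.0:
            raise ConfigError(
                "rest_duration_min must be >= 5 s (study design minimum)")
        if self.rest_duration_max < self.rest_duration_min:
            raise ConfigError("rest_duration_max below rest_duration_min")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ConfigError("invalid_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.ramp_shape not in ("linear", "half_cosine"):
            raise ConfigError(
                f"ramp_shape must be 'linear' or 'half_cosine', "
                f"got {self.ramp_shape!r}")
        if not 0.0 <= self.noise_correlation < 1.0:
            raise ConfigError("noise_correlation must lie in [0, 1)")
        if self.switch_delay < 0:
            raise ConfigError("switch_delay must be >= 0")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reach_target"] = list(self.reach_target)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "reach_target" in d:
            d["reach_target"] = tuple(d["reach_target"])
        return cls(**d)


TASKS = ("unilateral", "bilateral")
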