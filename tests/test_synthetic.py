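"""Synthetic study generator: structure, determinism, signal content."""

import numpy as np
import pytest
from scipy import stats

from lrpdetect.config import ConfigError, StudyConfig
from lrpdetect.montage import CHANNELS_64
from lrpdetect.synthetic import (
    GenerationError,
    _make_noise,
    _ramp,
    _rng,
    generate_dataset,
    spatial_pattern,
    synthesize_trial_eeg,
    synthesize_trial_motion,
)

C1 = CHANNELS_64.index("C1")


class TestStudyStructure:
    def test_trials_per_subject_task(self, small_dataset, small_config):
        expected = small_config.n_sets_per_task \
            * small_config.n_trials_per_set
        for subject in small_dataset.subjects:
            for task in small_dataset.tasks:
                trials = small_dataset.subject_task(subject, task).trials
                assert len(trials) == expected
                assert set(trials["set_index"]) == set(
                    range(small_config.n_sets_per_task))

    def test_rest_periods_at_least_five_seconds(self, uni_cell):
        valid = uni_cell.trials[uni_cell.trials["valid"]]
        assert (valid["rest"] >= 5.0).all()

    def test_onsets_inside_recording(self, uni_cell):
        onsets = uni_cell.trials["true_onset"]
        assert (onsets > 0).all()
        assert (onsets < uni_cell.recording.duration).all()

    def test_event_consistency_per_valid_trial(self, uni_cell):
        """Every valid trial: one switch release then one button press."""
        ev = uni_cell.recording.events
        releases = ev.of_kind("switch_release")
        buttons = ev.of_kind("button_press")
        trials = uni_cell.trials
        assert len(releases) == len(trials)
        assert len(buttons) == len(trials)
        assert np.all(releases < buttons)
        # the release follows each trial's true onset by the switch delay
        assert np.allclose(releases - trials["true_onset"], 0.015)

    def test_determinism_bitwise(self, small_config):
        a = generate_dataset(small_config).subject_task(1, "bilateral")
        b = generate_dataset(small_config).subject_task(1, "bilateral")
        assert a.recording.samples.tobytes() == b.recording.samples.tobytes()
        assert a.recording.events.frame.equals(b.recording.events.frame)
        assert a.trials.equals(b.trials)
        assert all(x.positions.tobytes() == y.positions.tobytes()
                   for x, y in zip(a.motion, b.motion))

    def test_invalid_rate_matches_binomial(self):
        cfg = StudyConfig(n_subjects=1, invalid_fraction=0.1, seed=21)
        trials = generate_dataset(cfg).subject_task(0, "unilateral").trials
        n_invalid = int((~trials["valid"]).sum())
        lo, hi = stats.binom.interval(0.95, len(trials), 0.1)
        assert lo <= n_invalid <= hi
        invalid = trials[~trials["valid"]]
        assert (invalid["rest"] < 5.0).all()


class TestLrpInjection:
    def test_bilateral_pattern_symmetric(self):
        w = spatial_pattern("bilateral", CHANNELS_64)
        assert w[C1] == w[CHANNELS_64.index("C2")]
        assert w[CHANNELS_64.index("C3")] == w[CHANNELS_64.index("C4")]

    def test_unilateral_pattern_lateralized(self):
        """Right-arm trials load the left hemisphere, not the right."""
        w = spatial_pattern("unilateral", CHANNELS_64)
        assert abs(w[C1]) > abs(w[CHANNELS_64.index("C2")])
        assert abs(w[CHANNELS_64.index("C3")]) > abs(
            w[CHANNELS_64.index("C4")])

    def test_averaging_recovers_ramp_at_c1(self):
        """Trial averaging converges on the injected ramp template.

        The 1/f background noise (10 uV SD) leaves a standard error of
        10/sqrt(n) uV on the trial average, so recovering the template to
        within 0.1 x |amplitude| = 0.6 uV at every sample needs a few
        thousand trials; 6000 leaves a ~3 sigma margin.
        """
        cfg = StudyConfig(n_channels=48, seed=3)
        rng = np.random.default_rng(42)
        n = 6000
        acc = np.zeros(3000)
        for _ in range(n):
            seg = synthesize_trial_eeg(cfg, "unilateral", 5.0, rng,
                                       duration=6.0)
            acc += seg[C1]
        avg = acc / n
        ramp = _ramp(cfg, cfg.eeg_rate) * cfg.lrp_amplitude
        template = np.zeros_like(avg)
        i0 = int(round((5.0 - cfg.lrp_duration) * cfg.eeg_rate))
        template[i0:i0 + len(ramp)] = ramp
        assert np.max(np.abs(avg - template)) < 0.1 * abs(cfg.lrp_amplitude)

    def test_zero_amplitude_leaves_pure_noise(self):
        """With lrp_amplitude=0 the pre-onset epoch average is noise-level."""
        cfg = StudyConfig(n_channels=48, lrp_amplitude=0.0, seed=9)
        rng = np.random.default_rng(7)
        n = 120
        acc = np.zeros(3000)
        for _ in range(n):
            acc += synthesize_trial_eeg(cfg, "unilateral", 5.0, rng,
                                        duration=6.0)[C1]
        avg = acc / n
        pre = avg[:int(5.0 * cfg.eeg_rate)]
        sem = cfg.noise_sd / np.sqrt(n)
        assert abs(pre.mean()) < 3 * sem

    def test_variance_stationary_without_lrp(self):
        """No window-position effect in the noise-only signal."""
        cfg = StudyConfig(n_subjects=1, lrp_amplitude=0.0, seed=13)
        cell = generate_dataset(cfg).subject_task(0, "unilateral")
        rate = cell.recording.rate
        pre, post = [], []
        for r in cell.trials.itertuples():
            i = int(round(r.true_onset * rate))
            pre.append(cell.recording.samples[:, i - 500:i])
            post.append(cell.recording.samples[:, i:i + 500])
        ratio = np.var(np.concatenate(pre, axis=1)) \
            / np.var(np.concatenate(post, axis=1))
        assert 0.9 < ratio < 1.1

    def test_ramp_shapes_start_and_peak(self):
        for shape in ("linear", "half_cosine"):
            cfg = StudyConfig(ramp_shape=shape)
            ramp = _ramp(cfg, 500.0)
            n_up = int(cfg.lrp_duration * 500)
            assert ramp[0] == 0.0
            assert ramp[n_up] == 1.0
            assert ramp[-1] == pytest.approx(0.0, abs=1e-9)


class TestTrialMotion:
    def test_zero_jitter_constant_before_onset(self):
        cfg = StudyConfig(motion_jitter_sd=0.0)
        trace = synthesize_trial_motion(cfg, 6.0, np.random.default_rng(0),
                                        t_start=0.0)
        pre = trace.positions[:int(6.0 * cfg.motion_rate)]
        assert np.all(pre == 0.0)

    def test_reach_amplitude_closed_form(self):
        """Final displacement equals sqrt(300^2 + 250^2) = 390.5 mm."""
        cfg = StudyConfig(motion_jitter_sd=0.0)
        trace = synthesize_trial_motion(cfg, 6.0, np.random.default_rng(0),
                                        t_start=0.0, t_end=7.5)
        final = np.linalg.norm(trace.positions[-1])
        assert final == pytest.approx(np.sqrt(300**2 + 250**2), abs=0.01)

    def test_switch_release_delay(self):
        cfg = StudyConfig(switch_delay=0.03)
        trace = synthesize_trial_motion(cfg, 6.0, np.random.default_rng(0),
                                        t_start=0.0)
        assert trace.switch_release - 6.0 == pytest.approx(0.03)

    def test_onset_outside_bounds_rejected(self):
        cfg = StudyConfig()
        with pytest.raises(GenerationError):
            synthesize_trial_motion(cfg, 6.0, np.random.default_rng(0),
                                    t_start=6.5)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_subjects", 0),
        ("n_trials_per_set", -1),
        ("eeg_rate", 0.0),
        ("rest_duration_min", 4.0),
        ("invalid_fraction", 1.5),
        ("ramp_shape", "square"),
        ("noise_correlation", 1.0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field):
            StudyConfig(**{field: value})

    def test_eeg_onset_too_early_rejected(self):
        with pytest.raises(GenerationError):
            synthesize_trial_eeg(StudyConfig(), "unilateral", 2.0,
                                 np.random.default_rng(0))

    def test_noise_streams_independent_of_each_other(self):
        cfg = StudyConfig(seed=4)
        a = _make_noise(cfg, 1000, _rng(cfg, 0))
        b = _make_noise(cfg, 1000, _rng(cfg, 1))
        assert not np.array_equal(a, b)
        assert np.array_equal(a, _make_noise(cfg, 1000, _rng(cfg, 0)))
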