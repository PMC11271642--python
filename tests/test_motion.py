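"""Kinematic onset estimation: profile construction and backward search."""

import numpy as np
import pandas as pd
import pytest

from lrpdetect.config import StudyConfig
from lrpdetect.motion import (
    DegenerateTrialError,
    KinematicProfile,
    OnsetNotFoundError,
    annotate_dataset,
    estimate_onset,
    kinematic_profile,
    label_hand,
)
from lrpdetect.synthetic import (
    MotionTrace,
    generate_dataset,
    synthesize_trial_motion,
)


def make_trace(positions, rate=500.0, t_start=0.0, release=None, **kw):
    release = release if release is not None else \
        t_start + len(positions) / rate / 2
    return MotionTrace(positions=np.asarray(positions, float), rate=rate,
                       t_start=t_start, switch_release=release, **kw)


@pytest.fixture()
def reach_trace():
    cfg = StudyConfig(seed=5)
    return synthesize_trial_motion(cfg, 6.0, np.random.default_rng(3),
                                   t_start=0.0)


class TestKinematicProfile:
    def test_stationary_trace_distance_near_zero(self, rng):
        jitter = 0.2
        pos = rng.normal(0, jitter, size=(3000, 3))
        profile = kinematic_profile(make_trace(pos))
        # distance is the norm of re-zeroed 3-D jitter; 5 sigma bounds its
        # max over the trial (seeded)
        assert profile.distance.max() < 5 * jitter

    def test_moving_trial_velocity_max_exactly_one(self, reach_trace):
        profile = kinematic_profile(reach_trace)
        assert np.max(np.abs(profile.velocity)) == 1.0

    def test_constant_speed_ramp_filter_gain_one(self):
        """A 1 mm/sample ramp passes the 4 Hz low-pass with flat unit gain:
        the filtered velocity is constant (relative variation < 1%) in the
        steady state, away from the step transient."""
        n = 4000
        pos = np.zeros((n, 3))
        pos[500:, 0] = np.arange(n - 500) * 1.0   # starts after rest window
        profile = kinematic_profile(make_trace(pos))
        steady = profile.velocity[1500:3500]
        assert np.ptp(steady) / steady.mean() < 0.01
        # and the raw (unnormalized, unfiltered) slope really was 1 mm/sample
        assert np.allclose(np.diff(profile.distance[1500:3500]), 1.0)

    def test_product_is_distance_times_velocity(self, reach_trace):
        profile = kinematic_profile(reach_trace)
        assert np.allclose(profile.product,
                           profile.distance * profile.velocity)

    def test_no_movement_is_degenerate(self):
        with pytest.raises(DegenerateTrialError):
            kinematic_profile(make_trace(np.zeros((3000, 3))))

    def test_trace_shorter_than_rest_window_rejected(self):
        with pytest.raises(ValueError):
            kinematic_profile(make_trace(np.zeros((400, 3))))


class TestEstimateOnset:
    def test_recovers_generator_ground_truth(self, reach_trace):
        """Estimate lands within the mechanical switch delay (15 ms)."""
        profile = kinematic_profile(reach_trace)
        est = estimate_onset(profile, reach_trace.switch_release)
        assert abs(est.onset_time - 6.0) <= 0.020
        assert est.method_threshold == 0.6

    def test_onset_never_after_search_start(self, reach_trace):
        profile = kinematic_profile(reach_trace)
        est = estimate_onset(profile, reach_trace.switch_release)
        assert est.onset_time <= est.search_start

    def test_quiet_product_returns_search_start(self):
        """All-below-threshold product: the backward scan stops at once."""
        profile = KinematicProfile(distance=np.zeros(3000),
                                   velocity=np.zeros(3000),
                                   product=np.zeros(3000),
                                   rate=500.0, t_start=0.0)
        est = estimate_onset(profile, 3.0)
        assert est.onset_time == pytest.approx(3.0, abs=1 / 500)

    def test_no_sample_below_threshold_raises(self):
        profile = KinematicProfile(distance=np.full(3000, 50.0),
                                   velocity=np.ones(3000),
                                   product=np.full(3000, 50.0),
                                   rate=500.0, t_start=0.0)
        with pytest.raises(OnsetNotFoundError):
            estimate_onset(profile, 3.0)

    def test_shift_equivariance(self, reach_trace):
        """Translating the trace by dt shifts the estimate by exactly dt.

        dt is a whole number of samples so the shifted search start lands
        on the same grid point."""
        dt = 2.344    # 1172 samples at 500 Hz
        shifted = MotionTrace(positions=reach_trace.positions,
                              rate=reach_trace.rate,
                              t_start=reach_trace.t_start + dt,
                              switch_release=reach_trace.switch_release + dt)
        e0 = estimate_onset(kinematic_profile(reach_trace),
                            reach_trace.switch_release)
        e1 = estimate_onset(kinematic_profile(shifted),
                            shifted.switch_release)
        assert e1.onset_time - e0.onset_time == pytest.approx(dt, abs=1e-9)

    def test_scale_robustness_within_three_samples(self, reach_trace):
        doubled = MotionTrace(positions=reach_trace.positions * 2,
                              rate=reach_trace.rate,
                              t_start=reach_trace.t_start,
                              switch_release=reach_trace.switch_release)
        e0 = estimate_onset(kinematic_profile(reach_trace),
                            reach_trace.switch_release)
        e1 = estimate_onset(kinematic_profile(doubled),
                            doubled.switch_release)
        assert abs(e1.onset_time - e0.onset_time) <= 3 / reach_trace.rate


class TestAnnotateDataset:
    def test_one_marker_per_valid_trial(self, uni_cell):
        onsets = annotate_dataset(uni_cell)
        valid = uni_cell.trials[uni_cell.trials["valid"]]
        assert len(onsets) == len(valid)
        err = np.abs(onsets["onset"] - onsets["true_onset"])
        assert (err <= 0.020).all()

    def test_bilateral_uses_left_hand(self, bi_cell):
        assert label_hand("bilateral") == "left"
        assert label_hand("unilateral") == "right"
        onsets = annotate_dataset(bi_cell)
        assert len(onsets) == int(bi_cell.trials["valid"].sum())
        # removing the left-hand traces must break bilateral annotation
        stripped = type(bi_cell)(
            subject=bi_cell.subject, task=bi_cell.task,
            recording=bi_cell.recording,
            motion=[m for m in bi_cell.motion if m.hand == "right"],
            trials=bi_cell.trials)
        with pytest.raises(ValueError, match="missing"):
            annotate_dataset(stripped)

    def test_invalid_trials_excluded(self):
        cfg = StudyConfig(n_subjects=1, n_trials_per_set=10,
                          invalid_fraction=0.25, seed=29)
        cell = generate_dataset(cfg).subject_task(0, "unilateral")
        n_invalid = int((~cell.trials["valid"]).sum())
        assert n_invalid > 0   # seed chosen to exercise the exclusion
        onsets = annotate_dataset(cell)
        assert len(onsets) == len(cell.trials) - n_invalid

    def test_all_onsets_precede_switch_release(self, bi_cell):
        onsets = annotate_dataset(bi_cell)
        releases = {(m.set_index, m.trial_index): m.switch_release
                    for m in bi_cell.motion if m.hand == "left"}
        for r in onsets.itertuples():
            assert r.onset <= releases[(r.set_index, r.trial_index)]
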