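"""Shared fixtures: small seeded synthetic studies.

The study generator is the ground-truth oracle for most tests, so the
fixtures fix both the configuration and the seed; everything downstream is
deterministic.
"""

import numpy as np
import pytest

from lrpdetect.config import StudyConfig
from lrpdetect.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Two subjects, 3 sets of 6 trials: fast but structurally complete."""
    return StudyConfig(n_subjects=2, n_trials_per_set=6, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def uni_cell(small_dataset):
    return small_dataset.subject_task(0, "unilateral")


@pytest.fixture(scope="session")
def bi_cell(small_dataset):
    return small_dataset.subject_task(0, "bilateral")


@pytest.fixture()
def rng():
    """Fresh deterministic stream per test: results never depend on which
    other tests ran before."""
    return np.random.default_rng(20240)
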