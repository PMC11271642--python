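"""Transfer-condition evaluation with change-point relabeling.

A trained detector is applied to every window of held-out test trials,
emulating asynchronous online classification.  Because the true start of
movement planning varies between self-paced trials, per-window ground
truth is derived from the prediction sequence itself under fixed boundary
constraints: windows before [-2.00, -1.00] s are always NoLRP and
[-1.00, 0.00] s is always LRP, while inside the interval between those two
windows a label change point is located by scanning the predicted labels
backward from [-1.00, 0.00] s for the first run of three consecutive NoLRP
predictions.  Balanced accuracy (mean of TPR and TNR) is computed over all
pooled test windows of a fold.

Three train-test conditions probe cross-task transfer with leave-one-set-
out validation (3 splits x 8 subjects = 24 folds each):

* A ``unilateral-unilateral`` (no transfer, baseline),
* B ``bilateral-bilateral`` (no transfer),
* C ``bilateral-unilateral`` (cross-task transfer, the target setting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .config import TASKS
from .model import fit_intent_model
from .montage import Montage, apply_montage
from .motion import annotate_dataset
from .pipeline import (
    DEFAULT_GRID,
    InsufficientHistoryError,
    cut_windows,
    preprocess_window,
)

# grid indices of the relabeling interval boundaries
RANGE_FIRST = 60    # window [-2.00, -1.00] s (always NoLRP before it)
RANGE_LAST = 80     # window [-1.00, 0.00] s (always LRP)
RUN_LENGTH = 3

CONDITIONS = {
    "A": ("unilateral", "unilateral"),
    "B": ("bilateral", "bilateral"),
    "C": ("bilateral", "unilateral"),
}


def make_splits(n_sets: int = 3):
    """Leave-one-set-out train/test pairs over the measurement sets.

    Returns ``[(train_sets, test_set), ...]`` where every set is the test
    set exactly once and train/test are disjoint.
    """
    if n_sets != 3:
        raise ValueError(f"the study design has exactly 3 sets, got "
                         f"{n_sets}")
    sets = tuple(range(n_sets))
    return [(tuple(s for s in sets if s != test), test) for test in sets]


def relabel_trial(predictions: np.ndarray,
                  grid=DEFAULT_GRID) -> np.ndarray:
    """Ground-truth labels for one trial from its prediction sequence.

    ``predictions`` holds the 81 predicted labels (1 = LRP) on the
    canonical grid.  Scanning backward from window [-1.00, 0.00] s, the
    first run of three consecutive NoLRP predictions wholly inside the
    relabeling interval places the change point immediately after (later
    than) the run: all windows up to and including the run become NoLRP
    truth and all later windows LRP truth.  If no run exists, the whole
    interval is LRP (a long movement-planning phase).  The fixed boundary
    labels are applied last: windows before [-2.00, -1.00] s are NoLRP and
    [-1.00, 0.00] s is LRP.
    """
    preds = np.asarray(predictions).astype(int)
    if preds.shape != (grid.n_windows,):
        raise ValueError(
            f"expected {grid.n_windows} predictions on the canonical "
            f"grid, got shape {preds.shape}")
    truth = np.zeros(grid.n_windows, dtype=int)
    change_at = None   # last NoLRP index; truth flips to LRP after it
    for j in range(RANGE_LAST, RANGE_FIRST + RUN_LENGTH - 2, -1):
        if not preds[j - RUN_LENGTH + 1:j + 1].any():
            change_at = j
            break
    if change_at is None:
        truth[RANGE_FIRST:] = 1
    else:
        truth[change_at + 1:] = 1
    truth[:RANGE_FIRST] = 0
    truth[RANGE_LAST] = 1
    return truth


def relabel_trials(predictions: np.ndarray,
                   grid=DEFAULT_GRID) -> np.ndarray:
    """Vectorized :func:`relabel_trial` over (n_trials, 81) predictions."""
    preds = np.atleast_2d(np.asarray(predictions)).astype(bool)
    if preds.shape[1] != grid.n_windows:
        raise ValueError(f"expected {grid.n_windows} windows per trial")
    nolrp = ~preds
    # run3[:, j] - windows j-2, j-1, j all predicted NoLRP, run in range
    ends = np.arange(RANGE_FIRST + RUN_LENGTH - 1, RANGE_LAST + 1)
    run3 = np.ones((preds.shape[0], len(ends)), dtype=bool)
    for k in range(RUN_LENGTH):
        run3 &= nolrp[:, ends - k]
    has_run = run3.any(axis=1)
    # backward scan -> the run with the largest end index wins
    last_run_end = ends[len(ends) - 1 - np.argmax(run3[:, ::-1], axis=1)]
    boundary = np.where(has_run, last_run_end + 1, RANGE_FIRST)
    truth = np.arange(grid.n_windows)[None, :] >= boundary[:, None]
    truth[:, :RANGE_FIRST] = False
    truth[:, RANGE_LAST] = True
    # uint8 keeps exhaustive (2^21-pattern) sweeps memory-light
    return truth.astype(np.uint8)


def balanced_accuracy(predictions, truths):
    """Pooled balanced accuracy: ``(BA, TPR, TNR)`` with LRP positive.

    ``predictions`` and ``truths`` are equal-length label arrays (1 = LRP)
    pooled over all test-trial windows of a fold; both classes must occur
    in the truth.
    """
    p = np.asarray(predictions).astype(bool).ravel()
    t = np.asarray(truths).astype(bool).ravel()
    if p.shape != t.shape:
        raise ValueError("predictions and truths differ in length")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("a class is absent from the truth labels; "
                         "rates are undefined")
    tpr = float((p & t).sum() / n_pos)
    tnr = float((~p & ~t).sum() / n_neg)
    return (tpr + tnr) / 2.0, tpr, tnr


@dataclass(frozen=True)
class FoldResult:
    """Balanced accuracy of one train-test fold."""

    subject: int
    condition: str
    montage: str
    test_set: int
    ba: float
    tpr: float
    tnr: float
    n_trials: int
    n_windows: int

    def __post_init__(self) -> None:
        if abs(self.ba - (self.tpr + self.tnr) / 2.0) > 1e-12:
            raise ValueError("BA must equal (TPR + TNR) / 2")


@dataclass
class ConditionReport:
    """All fold results of one (condition, montage) cell."""

    condition: str
    montage: str
    results: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def summary(self) -> dict:
        bas = np.array([r.ba for r in self.results])
        return dict(condition=self.condition, montage=self.montage,
                    n_folds=len(self.results),
                    mean_ba=float(bas.mean()) if len(bas) else float("nan"),
                    sd_ba=float(bas.std(ddof=1)) if len(bas) > 1
                    else float("nan"))


def _fold_seed(seed: int, subject: int, test_set: int) -> int:
    state = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, subject, test_set]).generate_state(1)[0]
    return int(state % (2 ** 31))


def preprocess_trials(data, montage: Montage, grid=DEFAULT_GRID,
                      onset_source: str = "estimated") -> dict:
    """Preprocessed 81-window stacks for every usable trial of a cell.

    Applies the montage, labels onsets (kinematic estimate by default, or
    the generator's ground truth with ``onset_source="true"``), cuts the
    sliding-window grid, and preprocesses each window.  Returns a dict
    ``(set_index, trial_index) -> (81, channels, 20)``; trials without
    enough pre-onset history are skipped.
    """
    rec = apply_montage(data.recording, montage)
    if onset_source == "estimated":
        onsets = annotate_dataset(data)
    elif onset_source == "true":
        valid = data.trials[data.trials["valid"]]
        onsets = valid.rename(columns={"true_onset": "onset"})[
            ["set_index", "trial_index", "onset"]]
    else:
        raise ValueError("onset_source must be 'estimated' or 'true'")
    out = {}
    for r in onsets.itertuples():
        try:
            raw = cut_windows(rec, r.onset, grid)
        except InsufficientHistoryError:
            continue
        out[(r.set_index, r.trial_index)] = preprocess_window(
            raw, rate=rec.rate)
    return out


def run_condition(dataset, condition: str, montage: Montage, seed: int = 0,
                  grid=DEFAULT_GRID,
                  onset_source: str = "estimated") -> ConditionReport:
    """Evaluate one train-test condition over all subjects and splits.

    For every subject and leave-one-set-out split, the detector is fitted
    on the condition's training task/sets (all artifacts — xDAWN filters,
    feature normalizer, SVM, Platt sigmoid — from training data only) and
    applied to every window of the held-out set of the test task.  In
    condition C the training trials are bilateral and the test trials
    unilateral (cross-task transfer).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of "
                         f"{sorted(CONDITIONS)}, got {condition!r}")
    train_task, test_task = CONDITIONS[condition]
    for task in {train_task, test_task}:
        if task not in TASKS:
            raise ValueError(f"dataset lacks task {task!r}")
    report = ConditionReport(condition=condition, montage=montage.name)
    splits = make_splits(dataset.config.n_sets_per_task)
    for subject in dataset.subjects:
        train_windows = preprocess_trials(
            dataset.subject_task(subject, train_task), montage, grid,
            onset_source)
        if test_task == train_task:
            test_windows = train_windows
        else:
            test_windows = preprocess_trials(
                dataset.subject_task(subject, test_task), montage, grid,
                onset_source)
        for train_sets, test_set in splits:
            fold_tag = f"s{subject}-{condition}-test{test_set}"
            trial_stack = [w for (s, _), w in sorted(train_windows.items())
                           if s in train_sets]
            model = fit_intent_model(
                trial_stack, montage_name=montage.name,
                seed=_fold_seed(seed, subject, test_set),
                grid=grid, fold_tag=fold_tag)
            preds, truths = [], []
            n_trials = 0
            for (s, _), w in sorted(test_windows.items()):
                if s != test_set:
                    continue
                p = model.predict(w)
                preds.append(p)
                truths.append(relabel_trial(p, grid))
                n_trials += 1
            ba, tpr, tnr = balanced_accuracy(np.concatenate(preds),
                                             np.concatenate(truths))
            report.results.append(FoldResult(
                subject=subject, condition=condition, montage=montage.name,
                test_set=test_set, ba=ba, tpr=tpr, tnr=tnr,
                n_trials=n_trials,
                n_windows=n_trials * grid.n_windows))
    return report
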