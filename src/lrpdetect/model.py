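"""Training-set assembly, L1-SVM training, and Platt calibration.

Per valid trial, five designated windows of the 81-window grid form the
training instances: [-1.10, -0.10] s and [-1.00, 0.00] s as LRP (movement
intention) and [-3.05, -2.05] s, [-3.25, -2.25] s, [-3.50, -2.50] s as
NoLRP (rest).  A linear SVM with L1 regularization is trained with class
weights 1:2 (NoLRP:LRP); its complexity parameter is selected by 5-fold
cross-validation over the 7 log-equispaced values 1e-6 ... 1e0 (scored by
balanced accuracy, ties resolved toward the smaller C).  Decision values
are mapped to probabilities with Platt's sigmoid; a probability strictly
greater than 0.5 signals a detected intention to move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .pipeline import (
    DEFAULT_GRID,
    FeatureNormalizer,
    XdawnFilter,
    apply_xdawn,
    extract_features,
    fit_xdawn,
)

LRP_TRAIN_STARTS = (-1.10, -1.00)
NOLRP_TRAIN_STARTS = (-3.50, -3.25, -3.05)
C_GRID = tuple(10.0 ** k for k in range(-6, 1))
CLASS_WEIGHTS = {0: 1.0, 1: 2.0}   # NoLRP : LRP = 1 : 2
DECISION_THRESHOLD = 0.5


def training_window_indices(grid=DEFAULT_GRID):
    """Grid indices of the designated LRP and NoLRP training windows."""
    lrp = tuple(grid.index_of(s) for s in LRP_TRAIN_STARTS)
    nolrp = tuple(grid.index_of(s) for s in NOLRP_TRAIN_STARTS)
    return lrp, nolrp


def assemble_training_set(trial_windows, grid=DEFAULT_GRID):
    """Select the 5 designated training windows per trial and label them.

    ``trial_windows`` is a sequence of per-trial arrays shaped
    (81, channels, time) (preprocessed windows on the canonical grid).
    Returns ``(windows, labels)`` with labels 1 = LRP, 0 = NoLRP; each
    trial contributes exactly 2 LRP and 3 NoLRP instances.
    """
    trial_windows = list(trial_windows)
    if not trial_windows:
        raise ValueError("no trials to assemble a training set from")
    lrp_idx, nolrp_idx = training_window_indices(grid)
    xs, ys = [], []
    for w in trial_windows:
        if w.shape[0] != grid.n_windows:
            raise ValueError(
                f"trial has {w.shape[0]} windows, expected "
                f"{grid.n_windows}")
        for i in lrp_idx:
            xs.append(w[i])
            ys.append(1)
        for i in nolrp_idx:
            xs.append(w[i])
            ys.append(0)
    return np.stack(xs), np.array(ys)


def _fit_platt(scores: np.ndarray, labels: np.ndarray):
    """Platt's sigmoid fit: P(LRP | s) = 1 / (1 + exp(a*s + b)).

    Maximum-likelihood fit with Platt's smoothed targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), solved with BFGS.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad(ab):
        a, b = ab
        z = a * s + b
        # p = sigmoid(-z); stable log-likelihood via logaddexp
        nll = np.sum(t * np.logaddexp(0.0, z)
                     + (1.0 - t) * np.logaddexp(0.0, -z))
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        d = t - p          # d(nll)/dz = t - sigmoid(-z)
        return nll, np.array([np.sum(d * s), np.sum(d)])

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = optimize.minimize(nll_grad, x0=np.array([0.0, b0]), jac=True,
                            method="BFGS")
    return float(res.x[0]), float(res.x[1])


@dataclass
class SvmModel:
    """Trained L1-SVM with Platt calibration over 16 features."""

    coef: np.ndarray
    intercept: float
    C: float
    platt_a: float
    platt_b: float
    cv_scores: dict = field(default_factory=dict)
    fold_tag: str = ""

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if f.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"expected {self.coef.shape[0]} features, got {f.shape[1]}")
        return f @ self.coef + self.intercept

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = self.platt_a * self.decision_values(features) + self.platt_b
        return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_proba(features)
                > DECISION_THRESHOLD).astype(int)


def train_model(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                c_grid=C_GRID, n_folds: int = 5,
                class_weights: dict = None, fold_tag: str = "") -> SvmModel:
    """Grid-searched L1-SVM with 1:2 class weights and Platt calibration.

    The complexity C is chosen by stratified ``n_folds``-fold CV over
    ``c_grid`` scored by balanced accuracy (ties -> smaller C); the final
    SVM is refit on the whole training set and a Platt sigmoid is fitted
    on its decision values.
    """
    if class_weights is None:
        class_weights = CLASS_WEIGHTS
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    counts = np.bincount(y)
    if counts[counts > 0].min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} instances per class for "
            f"{n_folds}-fold cross-validation")

    def make_svm(c):
        return LinearSVC(C=c, penalty="l1", loss="squared_hinge",
                         dual=False, class_weight=class_weights,
                         max_iter=20000, tol=1e-5, random_state=seed)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(x, y))
    cv_scores = {}
    for c in c_grid:
        scores = []
        for tr, te in splits:
            svm = make_svm(c).fit(x[tr], y[tr])
            scores.append(balanced_accuracy_score(y[te], svm.predict(x[te])))
        cv_scores[c] = float(np.mean(scores))
    # ties resolve to the smaller C (dict preserves ascending grid order)
    best_c = max(cv_scores, key=lambda c: (cv_scores[c], -c))
    svm = make_svm(best_c).fit(x, y)
    scores = x @ svm.coef_.ravel() + float(svm.intercept_[0])
    a, b = _fit_platt(scores, y)
    return SvmModel(coef=svm.coef_.ravel().copy(),
                    intercept=float(svm.intercept_[0]), C=float(best_c),
                    platt_a=a, platt_b=b, cv_scores=cv_scores,
                    fold_tag=fold_tag)


@dataclass
class IntentModel:
    """The full trained detector for one training fold.

    Bundles the montage name, the xDAWN filters, the feature normalizer,
    and the calibrated L1-SVM; transforms preprocessed windows straight to
    LRP probabilities.
    """

    montage_name: str
    xdawn: XdawnFilter
    normalizer: FeatureNormalizer
    svm: SvmModel
    fold_tag: str = ""

    def features(self, preprocessed_windows: np.ndarray) -> np.ndarray:
        pseudo = apply_xdawn(preprocessed_windows, self.xdawn)
        return extract_features(pseudo, normalizer=self.normalizer)

    def predict_proba(self, preprocessed_windows: np.ndarray) -> np.ndarray:
        return self.svm.predict_proba(self.features(preprocessed_windows))

    def predict(self, preprocessed_windows: np.ndarray) -> np.ndarray:
        return (self.predict_proba(preprocessed_windows)
                > DECISION_THRESHOLD).astype(int)

    def save(self, path) -> None:
        meta = dict(montage_name=self.montage_name, fold_tag=self.fold_tag,
                    C=self.svm.C, platt_a=self.svm.platt_a,
                    platt_b=self.svm.platt_b, intercept=self.svm.intercept,
                    xdawn_fold_tag=self.xdawn.fold_tag,
                    cv_scores={str(k): v
                               for k, v in self.svm.cv_scores.items()})
        np.savez(path,
                 xdawn_weights=self.xdawn.weights,
                 xdawn_eigenvalues=self.xdawn.eigenvalues,
                 norm_mean=self.normalizer.mean,
                 norm_sd=self.normalizer.sd,
                 svm_coef=self.svm.coef,
                 meta=np.frombuffer(
                     json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "IntentModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            xdawn = XdawnFilter(weights=z["xdawn_weights"],
                                eigenvalues=z["xdawn_eigenvalues"],
                                fold_tag=meta["xdawn_fold_tag"])
            normalizer = FeatureNormalizer(mean=z["norm_mean"],
                                           sd=z["norm_sd"],
                                           fold_tag=meta["fold_tag"])
            svm = SvmModel(coef=z["svm_coef"], intercept=meta["intercept"],
                           C=meta["C"], platt_a=meta["platt_a"],
                           platt_b=meta["platt_b"],
                           cv_scores={float(k): v for k, v in
                                      meta["cv_scores"].items()},
                           fold_tag=meta["fold_tag"])
        return cls(montage_name=meta["montage_name"], xdawn=xdawn,
                   normalizer=normalizer, svm=svm,
                   fold_tag=meta["fold_tag"])


def fit_intent_model(trial_windows, montage_name: str = "", seed: int = 0,
                     grid=DEFAULT_GRID, fold_tag: str = "") -> IntentModel:
    """Fit the full detector on the training trials of one fold.

    ``trial_windows`` holds per-trial preprocessed window stacks
    (81, channels, 20).  All fitted artifacts (xDAWN filters, feature
    normalizer, SVM, Platt sigmoid) derive from these trials only.
    """
    windows, labels = assemble_training_set(trial_windows, grid)
    xdawn = fit_xdawn(windows, labels, fold_tag=fold_tag)
    pseudo = apply_xdawn(windows, xdawn)
    raw_feats = extract_features(pseudo)
    normalizer = FeatureNormalizer.fit(raw_feats, fold_tag=fold_tag)
    svm = train_model(normalizer.transform(raw_feats), labels, seed=seed,
                      fold_tag=fold_tag)
    return IntentModel(montage_name=montage_name, xdawn=xdawn,
                       normalizer=normalizer, svm=svm, fold_tag=fold_tag)
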