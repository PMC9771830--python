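"""Cross-validated multinomial decoding of walking direction.

One session's example set is split into three contiguous temporal folds.
For each fold the classifier — multinomial logistic regression with L2
penalty, C = 1, tolerance 1e-4 and at most 1000 iterations — is trained on
the other folds after upsampling under-represented classes to a balanced
training set, and class probabilities are collected for the held-out fold.
The headline statistic is balanced accuracy (mean per-class recall) pooled
over the concatenated held-out predictions; chance for six direction bins
is 1/6 (16.66%). Significance per session comes from a permutation null:
the whole cross-validation repeated with training labels shuffled.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score

from .events import ExampleSet

CHANCE_LEVEL = 1.0 / 6.0  # six direction classes; displayed as 16.66%


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """Multinomial logistic-regression settings."""

    inverse_regularization_C: float = 1.0
    tolerance: float = 1e-4
    max_iterations: int = 1000

    def __post_init__(self):
        if not self.inverse_regularization_C > 0:
            raise ValueError("C must be positive")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")

    def build(self) -> LogisticRegression:
        # L2 is sklearn's default penalty; multinomial objective under lbfgs
        return LogisticRegression(
            C=self.inverse_regularization_C,
            tol=self.tolerance,
            max_iter=self.max_iterations,
            solver="lbfgs",
        )


@dataclasses.dataclass
class FoldAssignment:
    """Partition of a session's examples into k temporal folds."""

    k: int
    fold_of_example: np.ndarray  # fold index per example

    def __post_init__(self):
        sizes = np.bincount(self.fold_of_example, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")


@dataclasses.dataclass
class DecodingResult:
    """Pooled cross-validation outcome for one session."""

    balanced_accuracy: float  # pooled over folds, in [0, 1]
    per_fold_scores: np.ndarray
    prob: np.ndarray  # held-out examples x classes, rows sum to 1
    y_true: np.ndarray
    y_pred: np.ndarray
    classes: np.ndarray


@dataclasses.dataclass
class PermutationNull:
    """Null distribution of balanced accuracy under shuffled training labels."""

    scores: np.ndarray
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.scores)


def make_folds(es: ExampleSet, k: int = 3) -> FoldAssignment:
    """Contiguous temporal folds: examples sorted by onset, split into k runs.

    When len(es) is not divisible by k the earlier folds take the remainder
    (e.g. 10 examples -> 4/3/3). Deterministic; input order is irrelevant.
    """
    n = len(es.X)
    if n < k:
        raise ValueError(f"need at least {k} examples for {k} folds")
    order = np.argsort(es.onsets, kind="stable")
    fold_of_example = np.empty(n, dtype=int)
    for f, members in enumerate(np.array_split(order, k)):
        fold_of_example[members] = f
    return FoldAssignment(k, fold_of_example)


def upsample_to_balance(train_X, train_y, seed=None):
    """Balance class counts by duplicating under-represented classes.

    Every original row is retained; each minority class gains rows sampled
    with replacement (seeded) until all classes match the majority count.
    """
    train_X = np.asarray(train_X)
    train_y = np.asarray(train_y)
    classes, counts = np.unique(train_y, return_counts=True)
    if len(classes) == 0:
        raise ValueError("empty training set")
    target = counts.max()
    if np.all(counts == target):
        return train_X, train_y
    rng = np.random.default_rng(seed)
    extra_idx = []
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            members = np.flatnonzero(train_y == cls)
            extra_idx.append(rng.choice(members, size=target - cnt, replace=True))
    extra = np.concatenate(extra_idx)
    return np.vstack([train_X, train_X[extra]]), np.concatenate([train_y, train_y[extra]])


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recall over classes present in y_true."""
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("balanced accuracy of an empty prediction set")
    return float(balanced_accuracy_score(y_true, y_pred))


def cross_validate(
    es: ExampleSet,
    spec: ClassifierSpec = ClassifierSpec(),
    folds: FoldAssignment | None = None,
    seed=None,
    _permute_train: np.random.Generator | None = None,
) -> DecodingResult:
    """Run the full 3-fold within-session decoding procedure.

    Per fold: upsample the training classes to balance, fit, and collect
    held-out class probabilities. Results are pooled: balanced accuracy is
    computed on the concatenated held-out predictions; per-fold scores are
    reported alongside. Non-convergence at the iteration cap is a warning,
    not an error (the iteration budget is part of the classifier contract).
    """
    if folds is None:
        folds = make_folds(es)
    rng = np.random.default_rng(seed)
    classes = np.sort(np.asarray(es.classes, dtype=float))
    all_true, all_pred, all_prob, fold_scores = [], [], [], []
    for f in range(folds.k):
        test_mask = folds.fold_of_example == f
        train_X, train_y = es.X[~test_mask], es.y[~test_mask]
        if _permute_train is not None:
            train_y = _permute_train.permutation(train_y)
        if len(np.unique(train_y)) < len(classes):
            raise ValueError("a class is absent from the training set")
        train_X, train_y = upsample_to_balance(train_X, train_y, rng)
        clf = spec.build()
        with warnings.catch_warnings():
            # non-convergence at the iteration cap is acceptable by contract
            warnings.simplefilter("once", ConvergenceWarning)
            clf.fit(train_X, train_y)
        prob = clf.predict_proba(es.X[test_mask])
        # align probability columns to the canonical sorted class order
        col = np.searchsorted(classes, clf.classes_)
        aligned = np.empty((prob.shape[0], len(classes)))
        aligned[:, col] = prob
        pred = classes[np.argmax(aligned, axis=1)]
        truth = es.y[test_mask]
        all_true.append(truth)
        all_pred.append(pred)
        all_prob.append(aligned)
        fold_scores.append(balanced_accuracy(truth, pred))
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    return DecodingResult(
        balanced_accuracy(y_true, y_pred),
        np.array(fold_scores),
        np.vstack(all_prob),
        y_true,
        y_pred,
        classes,
    )


def permutation_null(
    es: ExampleSet,
    spec: ClassifierSpec = ClassifierSpec(),
    folds: FoldAssignment | None = None,
    n: int = 1000,
    seed=None,
) -> PermutationNull:
    """Null distribution: n repetitions of cross_validate with training
    labels permuted independently per iteration. Test labels are untouched
    and still define the scoring."""
    if folds is None:
        folds = make_folds(es)
    root = np.random.default_rng(seed)
    scores = np.empty(n)
    for i in range(n):
        perm_rng = np.random.default_rng(root.integers(2**31))
        up_rng = np.random.default_rng(root.integers(2**31))
        result = cross_validate(es, spec, folds, seed=up_rng, _permute_train=perm_rng)
        scores[i] = result.balanced_accuracy
    return PermutationNull(scores, seed if isinstance(seed, int) else None)


def group_null_of_means(per_subject_nulls: Sequence[PermutationNull]) -> np.ndarray:
    """Iteration-wise mean across subjects' permutation nulls.

    Mirrors the group averaging of the true scores: iteration i of the group
    null is the mean of every subject's i-th null score.
    """
    lengths = {null.n_iterations for null in per_subject_nulls}
    if len(lengths) != 1:
        raise ValueError("all subjects must have the same number of iterations")
    return np.mean([null.scores for null in per_subject_nulls], axis=0)
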