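"""Linear classification of AD vs HC from per-person entropy features.

For each subject the SampEn of both signatures at a fixed (m, r_rel) cell
forms the feature vector (two columns per channel).  A linear SVM or LDA is
evaluated under stratified two-fold cross-validation: train on one half,
predict the other, swap, and pool the held-out predictions into a single
confusion matrix.  Features are standardized with training-fold statistics
only.  Sensitivity is the fraction of AD patients correctly detected,
specificity the fraction of controls; both are judged against the a-priori
group probabilities (the base rates any classifier must beat).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .sampen import max_resolvable_entropy

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL_SETS: tuple[tuple[str, ...], ...] = (
    ("p",),
    ("Alt",),
    ("p", "Alt"),
    ("x", "y", "p", "Alt"),
)


@dataclass
class FeatureMatrix:
    """Per-subject entropy features: (SE of signature 1, SE of signature 2)
    for each channel in ``channel_set``, plus AD/HC labels."""

    X: np.ndarray
    y: np.ndarray  # 1 = AD, 0 = HC
    subject_ids: list[str]
    channel_set: tuple[str, ...]
    m: int
    r_rel: float
    n_capped: int = 0

    def __post_init__(self) -> None:
        if self.X.shape[1] != 2 * len(self.channel_set):
            raise ValueError("column count must be 2 * |channel_set|")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains undefined entries")


@dataclass
class ClassificationReport:
    classifier: str
    channel_set: tuple[str, ...]
    tp: int  # AD correctly detected
    fn: int
    tn: int  # HC correctly detected
    fp: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    seed: int
    repeats: int
    per_repeat: list[dict] = field(default_factory=list)
    rate_sd: dict | None = None
    pooling: str = "held-out predictions of both folds pooled into one confusion matrix"

    def __post_init__(self) -> None:
        n_ad = self.tp + self.fn
        n_hc = self.tn + self.fp
        if n_ad <= 0 or n_hc <= 0:
            raise ValueError("empty class in confusion counts")
        for rate in (self.sensitivity, self.specificity, self.accuracy):
            if not 0 <= rate <= 100:
                raise ValueError("rates must be percentages in [0, 100]")
        expect = (self.sensitivity * n_ad + self.specificity * n_hc) / (n_ad + n_hc)
        if abs(expect - self.accuracy) > 1e-9:
            raise ValueError("accuracy inconsistent with class rates and sizes")


def rates_from_counts(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent from confusion
    counts; AD is the positive class."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("each class needs at least one member")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    return sens, spec, acc


def prior_baseline(n_ad: int, n_hc: int) -> tuple[float, float]:
    """A-priori group probabilities (p_ad, p_hc)."""
    n = n_ad + n_hc
    if n_ad < 1 or n_hc < 1:
        raise ValueError("both groups must be non-empty")
    return n_ad / n, n_hc / n


def prior_relative_improvement(rate: float, prior: float) -> float:
    """100 * (rate - prior) / prior, with rate and prior on the same scale
    (both fractions or both percentages)."""
    if prior <= 0:
        raise ValueError("prior must be > 0")
    return 100.0 * (rate - prior) / prior


def build_features(
    table: pd.DataFrame,
    channel_set: Sequence[str],
    m: int = 3,
    r_rel: float = 0.1,
    undefined_policy: str = "cap",
) -> FeatureMatrix:
    """Feature matrix from a cohort table built at the fixed cell (m, r_rel).

    Undefined SampEn values (A = 0: no template pair survived extension)
    signal maximal irregularity; under the default ``cap`` policy they are
    replaced by the maximum resolvable entropy ln((N-m)(N-m-1)/2) for that
    signature's length N.  ``drop`` removes the subject instead.
    """
    if undefined_policy not in ("cap", "drop"):
        raise ValueError(f"unknown undefined_policy {undefined_policy!r}")
    channel_set = tuple(channel_set)
    for ch in channel_set:
        for inst in (1, 2):
            if f"SE{inst}_{ch}" not in table.columns:
                raise ValueError(f"channel {ch!r} not computed in table")
    cols = [f"SE{inst}_{ch}" for ch in channel_set for inst in (1, 2)]
    X = table[cols].to_numpy(dtype=float)
    n_capped = 0
    if undefined_policy == "cap":
        for j, col in enumerate(cols):
            inst = int(col[2])
            nan_rows = np.flatnonzero(np.isnan(X[:, j]))
            for i in nan_rows:
                n = int(table[f"n_samples_{inst}"].iloc[i])
                X[i, j] = max_resolvable_entropy(n, m)
                n_capped += 1
                logger.warning(
                    "capped undefined SampEn for subject %s (%s) at %.3f",
                    table["subject_id"].iloc[i],
                    col,
                    X[i, j],
                )
        keep = np.ones(len(table), dtype=bool)
    else:
        keep = ~np.isnan(X).any(axis=1)
        if not keep.any():
            raise ValueError("all subjects dropped by undefined_policy='drop'")
        X = X[keep]
    y = (table["group"].to_numpy() == "AD").astype(int)[keep]
    ids = table["subject_id"].to_numpy()[keep].tolist()
    return FeatureMatrix(
        X=X,
        y=y,
        subject_ids=ids,
        channel_set=channel_set,
        m=m,
        r_rel=r_rel,
        n_capped=n_capped,
    )


def _make_classifier(name: str, C: float = 1.0):
    if name == "linear_svm":
        return SVC(kernel="linear", C=C)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {name!r}")


def _stratified_halves(
    y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified 50/50 split; each class divided as evenly as the
    parity allows."""
    fold = np.zeros(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx[: idx.size // 2]] = 1
    return np.flatnonzero(fold == 0), np.flatnonzero(fold == 1)


def two_fold_cv(
    features: FeatureMatrix,
    classifier: str = "linear_svm",
    seed: int = 0,
    repeats: int = 1,
    C: float = 1.0,
) -> ClassificationReport:
    """Stratified two-fold cross-validation, held-out predictions pooled.

    Standardization (zero mean, unit variance) is fit on the training fold
    only; zero-variance features in a training fold are dropped for that
    fold with a warning.  With ``repeats`` > 1, the split is redrawn each
    repeat and per-repeat rates plus their mean and sd are reported; the
    headline confusion counts come from the first repeat.
    """
    X, y = features.X, features.y
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    per_repeat = []
    first_counts = None
    for rep in range(repeats):
        fold_a, fold_b = _stratified_halves(y, rng)
        y_true = np.empty(0, dtype=int)
        y_pred = np.empty(0, dtype=int)
        for train_idx, test_idx in ((fold_a, fold_b), (fold_b, fold_a)):
            mu = X[train_idx].mean(axis=0)
            sd = X[train_idx].std(axis=0)
            usable = sd > 0
            if not usable.all():
                warnings.warn("zero-variance feature dropped in a training fold")
            if not usable.any():
                raise ValueError("no usable features after variance screening")
            Xtr = (X[train_idx][:, usable] - mu[usable]) / sd[usable]
            Xte = (X[test_idx][:, usable] - mu[usable]) / sd[usable]
            clf = _make_classifier(classifier, C=C)
            clf.fit(Xtr, y[train_idx])
            y_true = np.concatenate([y_true, y[test_idx]])
            y_pred = np.concatenate([y_pred, clf.predict(Xte)])
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        sens, spec, acc = rates_from_counts(tp, fn, tn, fp)
        per_repeat.append(
            {
                "tp": tp,
                "fn": fn,
                "tn": tn,
                "fp": fp,
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
            }
        )
        if first_counts is None:
            first_counts = (tp, fn, tn, fp)
    tp, fn, tn, fp = first_counts
    sens, spec, acc = rates_from_counts(tp, fn, tn, fp)
    rate_sd = None
    if repeats > 1:
        rate_sd = {
            key: {
                "mean": float(np.mean([r[key] for r in per_repeat])),
                "sd": float(np.std([r[key] for r in per_repeat], ddof=1)),
            }
            for key in ("sensitivity", "specificity", "accuracy")
        }
    return ClassificationReport(
        classifier=classifier,
        channel_set=features.channel_set,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        seed=seed,
        repeats=repeats,
        per_repeat=per_repeat,
        rate_sd=rate_sd,
    )
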