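"""Cross-validation splitting, fold training, and evaluation metrics.

Evaluation follows the protocol used for magnification comparisons on
bone marrow smear cohorts: 5-fold *Monte Carlo* cross-validation — each
fold is an independent stratified 60/20/20 train/validation/test
resample, not a disjoint k-fold partition — scored with the
macro-averaged one-vs-rest AUC, balanced error, prediction-confidence
summaries, and a 2-D PCA of slide-level representations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .mil import GatedAttentionMIL

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "MAGNIFICATION_PRESETS",
    "monte_carlo_split",
    "train_fold",
    "evaluate",
    "macro_ovr_auc",
    "balanced_error",
    "confidence_summary",
    "slide_feature_pca",
]

# instance-cluster sample size B per objective magnification
MAGNIFICATION_PRESETS = {"10x": 8, "40x": 32, "100x": 128}


@dataclass
class FoldSplit:
    """One Monte Carlo fold: disjoint, stratified train/val/test ids."""

    fold_id: int
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = ([(self.fold_id, i, "train") for i in self.train_ids]
                + [(self.fold_id, i, "val") for i in self.val_ids]
                + [(self.fold_id, i, "test") for i in self.test_ids])
        return pd.DataFrame(rows, columns=["fold", "slide_id", "role"])


@dataclass
class MetricsReport:
    macro_ovr_auc: float
    per_class_auc: dict[int, float]
    balanced_error: float
    accuracy: float
    mean_confidence_correct: float | None
    sd_confidence_correct: float | None
    mean_confidence_incorrect: float | None
    sd_confidence_incorrect: float | None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_class_auc"] = {int(k): float(v)
                              for k, v in self.per_class_auc.items()}
        return d


def monte_carlo_split(
    labels,
    ids=None,
    n_folds: int = 5,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> list[FoldSplit]:
    """Independent stratified train/val/test resamples.

    Within each class of size ``n_c``: ``round(f_train * n_c)`` train,
    ``round(f_val * n_c)`` validation, the remainder test; every split
    gets at least one member per class (requires ``n_c >= 3``).  Each
    fold reshuffles independently from a seed derived from ``seed`` and
    the fold id, so folds overlap at random (Monte Carlo) but are exactly
    reproducible.
    """
    labels = np.asarray(labels)
    ids = np.arange(labels.size) if ids is None else np.asarray(ids)
    if ids.size != labels.size:
        raise ValueError("ids and labels must align")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        bad = classes[counts.argmin()]
        raise ValueError(
            f"class {bad!r} has {counts.min()} member(s); need >= 3 for "
            "nonempty train/val/test splits")
    folds = []
    for fold in range(1, n_folds + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, fold]))
        tr, va, te = [], [], []
        for c in classes:
            members = ids[labels == c]
            perm = rng.permutation(members)
            n_c = members.size
            n_tr = max(int(round(fractions[0] * n_c)), 1)
            n_va = max(int(round(fractions[1] * n_c)), 1)
            n_tr = min(n_tr, n_c - 2)          # leave room for val + test
            n_va = min(n_va, n_c - n_tr - 1)   # leave room for test
            tr.extend(perm[:n_tr])
            va.extend(perm[n_tr:n_tr + n_va])
            te.extend(perm[n_tr + n_va:])
        folds.append(FoldSplit(fold_id=fold,
                               train_ids=np.asarray(tr),
                               val_ids=np.asarray(va),
                               test_ids=np.asarray(te),
                               seed=seed))
    return folds


def train_fold(
    bags_by_id: dict,
    labels_by_id: dict,
    split: FoldSplit,
    **estimator_kwargs,
) -> GatedAttentionMIL:
    """Fit a :class:`GatedAttentionMIL` on one fold's train bags with its
    validation bags driving early stopping."""
    def gather(id_list):
        X = [bags_by_id[i] for i in id_list]
        y = [labels_by_id[i] for i in id_list]
        return X, np.asarray(y, dtype=np.int64)

    X_tr, y_tr = gather(split.train_ids)
    X_va, y_va = gather(split.val_ids)
    est = GatedAttentionMIL(**estimator_kwargs)
    return est.fit(X_tr, y_tr, val_X=X_va, val_y=y_va)


def macro_ovr_auc(probs: np.ndarray, labels) -> tuple[float, dict[int, float]]:
    """Macro-averaged one-vs-rest AUC.

    Per class i: AUC of the i-th probability column against the binary
    "is class i" labels; the macro value is the unweighted mean.  Classes
    without both a positive and a negative slide are skipped with a
    warning and excluded from the mean.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape[0] != labels.size or labels.size == 0:
        raise ValueError("probs must be n_slides x n_classes aligned with labels")
    if np.unique(labels).size < 2:
        raise ValueError("macro one-vs-rest AUC undefined with a single class")
    per_class: dict[int, float] = {}
    for c in range(probs.shape[1]):
        pos = labels == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} lacks positives or negatives; "
                          "skipped in macro AUC", stacklevel=2)
            continue
        per_class[c] = float(roc_auc_score(pos.astype(int), probs[:, c]))
    return float(np.mean(list(per_class.values()))), per_class


def balanced_error(predicted, labels) -> float:
    """Mean over observed classes of (1 - per-class recall)."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    errs = []
    for c in np.unique(labels):
        members = labels == c
        errs.append(1.0 - float(np.mean(predicted[members] == c)))
    return float(np.mean(errs))


def confidence_summary(probs: np.ndarray, predicted, labels):
    """Mean +/- sd of the winning probability, split by correctness.

    Returns ``((mean, sd) or None for correct, same for incorrect)``;
    an empty group reports ``None`` rather than zero.
    """
    probs = np.asarray(probs, dtype=np.float64)
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    conf = probs.max(axis=1)
    out = []
    for group in (predicted == labels, predicted != labels):
        if group.any():
            out.append((float(conf[group].mean()), float(conf[group].std())))
        else:
            out.append(None)
    return tuple(out)


def slide_feature_pca(representations: np.ndarray) -> np.ndarray:
    """Project slide-level representations onto their top-2 principal
    components (centered).  Degenerate (zero-variance) input returns
    all-zero coordinates."""
    X = np.asarray(representations, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 slides for PCA")
    if np.allclose(X, X[0]):
        return np.zeros((X.shape[0], 2))
    n_comp = min(2, X.shape[1], X.shape[0] - 1)
    coords = PCA(n_components=n_comp).fit_transform(X)
    if n_comp < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - n_comp)))
    return coords


def evaluate(
    estimator: GatedAttentionMIL,
    bags,
    labels,
) -> tuple[MetricsReport, np.ndarray]:
    """Score a fitted model on held-out bags; returns the metrics report
    and the probability table."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = estimator.predict_proba(bags)
    predicted = probs.argmax(axis=1)
    macro, per_class = macro_ovr_auc(probs, labels)
    correct, incorrect = confidence_summary(probs, predicted, labels)
    report = MetricsReport(
        macro_ovr_auc=macro,
        per_class_auc=per_class,
        balanced_error=balanced_error(predicted, labels),
        accuracy=float(np.mean(predicted == labels)),
        mean_confidence_correct=None if correct is None else correct[0],
        sd_confidence_correct=None if correct is None else correct[1],
        mean_confidence_incorrect=None if incorrect is None else incorrect[0],
        sd_confidence_incorrect=None if incorrect is None else incorrect[1],
    )
    return report, probs
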