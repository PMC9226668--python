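"""Desk-scale synthetic benchmark: the full generate → train → evaluate →
localize pipeline under one roof.

The benchmark emulates the study design used on real bone marrow smear
cohorts — five disease classes, bags of 30–70 instances, a 10x-preset
model trained with early stopping — but on synthetic feature bags with
known evidence instances, so slide-level discrimination *and*
attention-based evidence localization can both be scored exactly.  The
default problem size (25 train / 8 validation / 8 test bags per class,
256-d features) keeps a full run in the minutes range on one CPU while
leaving the class-recovery problem statistically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interpret import evidence_localization_score
from .mil import GatedAttentionMIL
from .syndata import SyntheticBagSpec, generate_feature_bags
from .training import evaluate

__all__ = ["BenchmarkResult", "run_synthetic_benchmark"]


@dataclass
class BenchmarkResult:
    macro_ovr_auc: float
    balanced_error: float
    accuracy: float
    mean_localization: float | None
    n_test_bags: int
    n_train_bags: int
    epochs_run: int
    estimator: GatedAttentionMIL
    report: object


def run_synthetic_benchmark(
    separation: float = 6.0,
    seed: int = 1,
    n_classes: int = 5,
    split_sizes: tuple[int, int, int] = (25, 8, 8),
    feature_dim: int = 256,
    evidence_fraction: float = 0.1,
    bag_size_range: tuple[int, int] = (30, 70),
    B: int = 8,
    learning_rate: float = 2e-4,
    max_epochs: int = 200,
    patience: int = 20,
    localization: bool = True,
) -> BenchmarkResult:
    """Train the classifier on synthetic bags and score it held-out.

    With ``separation`` = 6 (evidence instances six noise-sd away from
    background) the task is near-perfectly solvable; with 0 it is an
    exact null and the held-out macro AUC calibrates around 0.5.
    """
    spec = SyntheticBagSpec(
        n_classes=n_classes, bag_size_range=bag_size_range,
        evidence_fraction=evidence_fraction, feature_dim=feature_dim,
        separation=separation, seed=seed)
    train, val, test = generate_feature_bags(spec, split_sizes=split_sizes)

    def unpack(pairs):
        return ([b.features for b, _ in pairs],
                np.asarray([b.label for b, _ in pairs]),
                [t.evidence_flags for _, t in pairs])

    X_tr, y_tr, _ = unpack(train)
    X_va, y_va, _ = unpack(val)
    X_te, y_te, flags_te = unpack(test)

    est = GatedAttentionMIL(
        n_classes=n_classes, B=B, learning_rate=learning_rate,
        max_epochs=max_epochs, patience=patience, random_state=seed)
    est.fit(X_tr, y_tr, val_X=X_va, val_y=y_va)
    report, _ = evaluate(est, X_te, y_te)

    mean_loc = None
    if localization:
        scores = [evidence_localization_score(est.attention(x)[y], f)
                  for x, y, f in zip(X_te, y_te, flags_te)]
        mean_loc = float(np.mean(scores))

    return BenchmarkResult(
        macro_ovr_auc=report.macro_ovr_auc,
        balanced_error=report.balanced_error,
        accuracy=report.accuracy,
        mean_localization=mean_loc,
        n_test_bags=len(X_te),
        n_train_bags=len(X_tr),
        epochs_run=len(est.history_["epoch"]),
        estimator=est,
        report=report,
    )
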