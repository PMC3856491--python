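"""Stratified cross-validation, ROC/AUC, and the ranked-prediction
metric suite (SN, SP, FPR, PPV, NPV, F-measure, ACC, MCC).

The evaluation protocol mirrors how essential-protein predictors are
compared in practice: proteins are ranked by score, the top k (k = the
number of known essential proteins) are called essential, and the rate
metrics are computed from the resulting confusion counts. Note that with
k equal to the number of actual positives, TP + FP = TP + FN, which forces
SN = PPV and SP = NPV — a counting identity, not a coincidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .engine import ConfusionCounts, GepConfig, EvolveResult, confusion_at_k, evolve


@dataclass
class MetricReport:
    """Rate metrics of a ranked prediction, optionally with its ROC."""

    counts: ConfusionCounts | None = None
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def __getattr__(self, name):
        if name in ("sn", "sp", "ppv", "npv", "fpr", "f_measure", "acc", "mcc"):
            if self.counts is None:
                raise AttributeError(f"no confusion counts available for {name!r}")
            return getattr(self.counts, name)
        raise AttributeError(name)

    def row(self) -> dict[str, float]:
        """The standard comparison-table row."""
        out: dict[str, float] = {}
        if self.counts is not None:
            out.update(SN=self.sn, SP=self.sp, FPR=self.fpr, PPV=self.ppv,
                       NPV=self.npv, F_measure=self.f_measure, ACC=self.acc,
                       MCC=self.mcc)
        if self.auc is not None:
            out["AUC"] = self.auc
        return out


def stratified_kfold(labels: pd.Series, k: int,
                     rng: np.random.Generator | int | None = None) -> pd.Series:
    """Assign each protein to one of k folds, preserving the class ratio.

    Per class: shuffle then round-robin, so per-class fold sizes differ by
    at most one. Seeded and reproducible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = labels.astype(int)
    assignment = pd.Series(-1, index=labels.index, dtype=int)
    for cls in (1, 0):
        members = sorted(labels.index[labels == cls])
        if not members:
            raise ValueError(f"class {cls} has no members; cannot stratify")
        members = list(np.array(members)[rng.permutation(len(members))])
        for i, pid in enumerate(members):
            assignment[pid] = i % k
    return assignment


def roc_auc(scores: pd.Series, labels: pd.Series) -> MetricReport:
    """ROC curve over all score cutoffs and its trapezoidal AUC.

    Equal scores are grouped into a single step, so tied proteins receive
    half credit, matching the rank-sum (Mann-Whitney) interpretation.
    Raises if only one class is present.
    """
    y = labels.reindex(scores.index).to_numpy(dtype=int)
    s = scores.to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return MetricReport(auc=auc, roc_points=list(zip(fpr.tolist(), tpr.tolist())))


def topk_metrics(scores: pd.Series, labels: pd.Series, k: int) -> MetricReport:
    """Rate metrics of the rank-based split at cutoff k, plus the ROC/AUC
    when both classes are present."""
    if not 0 < k < len(scores):
        raise ValueError(f"k must be in (0, {len(scores)}), got {k}")
    counts = confusion_at_k(scores, labels, k)
    report = MetricReport(counts=counts)
    y = labels.reindex(scores.index).astype(int)
    if 0 < y.sum() < len(y):
        roc = roc_auc(scores, labels)
        report.auc = roc.auc
        report.roc_points = roc.roc_points
    return report


@dataclass
class FoldResult:
    fold: int
    evolve_result: EvolveResult
    report: MetricReport
    test_proteins: tuple[str, ...] = ()

    @property
    def auc(self) -> float:
        return self.report.auc


@dataclass
class CrossValidationReport:
    folds: list[FoldResult]
    assignment: pd.Series

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    def representative(self) -> FoldResult:
        """The fold classifier whose held-out AUC is closest to the mean
        (ties to the lower fold index) — the one used for whole-network
        scoring."""
        mean = self.mean_auc
        return min(self.folds, key=lambda f: (abs(f.auc - mean), f.fold))


def cross_validate(features: pd.DataFrame, labels: pd.Series, config: GepConfig,
                   k: int = 10,
                   rng: np.random.Generator | int | None = None) -> CrossValidationReport:
    """Stratified k-fold cross-validation of the GEP classifier.

    For each fold, evolve on the remaining k-1 folds, score the held-out
    proteins, and report the held-out AUC and rate metrics at the fold's
    positive count. Every protein is tested exactly once.
    """
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else rng)
    labels = labels.reindex(features.index).astype(int)
    assignment = stratified_kfold(labels, k, rng)
    folds: list[FoldResult] = []
    for fold in range(k):
        test_mask = assignment == fold
        train_x = features.loc[~test_mask]
        train_y = labels.loc[~test_mask]
        test_x = features.loc[test_mask]
        test_y = labels.loc[test_mask]
        result = evolve(train_x, train_y, config, rng=rng)
        tree = result.best_tree
        from . import karva
        scores = pd.Series(
            np.broadcast_to(
                np.asarray(karva.evaluate(tree, {c: test_x[c].to_numpy(dtype=float)
                                                 for c in test_x.columns}), dtype=float),
                (len(test_x),)).copy(),
            index=test_x.index)
        k_pos = int(test_y.sum())
        report = topk_metrics(scores, test_y, k_pos) if 0 < k_pos < len(test_y) \
            else roc_auc(scores, test_y)
        folds.append(FoldResult(fold=fold, evolve_result=result, report=report,
                                test_proteins=tuple(test_x.index)))
    return CrossValidationReport(folds=folds, assignment=assignment)
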