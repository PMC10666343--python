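"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, and the two
validation protocols used for the binder benchmark.

Metrics (all from the confusion counts TP, TN, FP, FN):

* ``SN = TP / (TP + FN)`` — sensitivity (true-positive rate),
* ``SP = TN / (TN + FP)`` — specificity,
* ``ACC = (TP + TN) / total`` — accuracy,
* ``MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN))`` — Matthews
  correlation; when any factor under the root is zero MCC is reported as 0
  with a warning flag (the common convention).

The ROC curve links the true-positive rate against the false-positive rate
at every distinct score threshold (anchored at (0,0) and (1,1)); AUC is its
trapezoidal integral, which equals the Mann–Whitney rank statistic with
ties counted one half.

Protocols: stratified k-fold cross-validation (optionally repeated) for the
balanced datasets, and repeated random 10 % hold-out for the imbalanced
ones; a two-sample Welch t-test compares per-repetition metric values
between methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ShapeError, TrainingError, UndefinedMetricError
from .network import ModelConfig, TrainedModel, build_variant, classify, train
from .peptide_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts for one evaluated split."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """SN/SP/ACC/MCC (and AUC when scores are available) for one split."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    #: set when an undefined quantity was reported under a convention
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | None]:
        return {"SN": self.sn, "SP": self.sp, "ACC": self.acc,
                "MCC": self.mcc, "AUC": self.auc}


def confusion(labels: Sequence[int], predictions: Sequence[int]
              ) -> ConfusionCounts:
    """Count TP/TN/FP/FN from binary labels and binary predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ShapeError(f"labels {y.shape} vs predictions {p.shape}")
    if y.size and (not np.isin(y, (0, 1)).all() or not np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """SN, SP, ACC and MCC from confusion counts (AUC left unset)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: list[str] = []

    if tp + fn == 0:
        sn = float("nan")
        flags.append("SN_undefined")
    else:
        sn = tp / (tp + fn)
    if tn + fp == 0:
        sp = float("nan")
        flags.append("SP_undefined")
    else:
        sp = tn / (tn + fp)
    if counts.total == 0:
        raise UndefinedMetricError("no samples to evaluate")
    acc = (tp + tn) / counts.total

    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        flags.append("MCC_zero_denominator")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc, flags=tuple(flags))


def roc_curve(labels: Sequence[int], scores: Sequence[float]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds) at every distinct score, anchored at the ends.

    Thresholds are the distinct scores in decreasing order; a point's TPR and
    FPR count predictions with score >= that threshold as positive.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ShapeError(f"labels {y.shape} vs scores {s.shape}")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied score block
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp_cum[last_of_block] / n_pos]
    fpr = np.r_[0.0, fp_cum[last_of_block] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[last_of_block]]
    return fpr, tpr, thresholds


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve (ties counted one half)."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ProtocolResult:
    """Per-split metrics plus their mean/sd summary for one protocol run."""

    protocol: str
    per_split: list[MetricSet]
    split_descriptors: list[dict] = field(default_factory=list)
    pooled_labels: np.ndarray | None = None
    pooled_scores: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.per_split]
        frame = pd.DataFrame(rows)
        frame.insert(0, "split", range(1, len(rows) + 1))
        return frame

    def summary(self) -> pd.DataFrame:
        frame = self.to_frame().drop(columns="split")
        return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})

    def mean(self, metric: str) -> float:
        return float(self.to_frame()[metric].mean())

    def pooled_auc(self) -> float:
        """AUC over the pooled out-of-split scores."""
        if self.pooled_labels is None or self.pooled_scores is None:
            raise UndefinedMetricError("no pooled scores recorded")
        return roc_auc(self.pooled_labels, self.pooled_scores)


def _evaluate_split(trained: TrainedModel, dataset: LabeledDataset,
                    test_idx: np.ndarray, threshold: float) -> tuple[MetricSet, np.ndarray]:
    from .encoders import encode_batch  # local to avoid cycle at import time

    records, y_test = dataset.subset(test_idx)
    x_test = encode_batch(records, trained.config.channels,
                          trained.config.l_max, trained.config.pad_value)
    scores = trained.predict_proba(x_test)
    counts = confusion(y_test, classify(scores, threshold))
    m = metrics(counts)
    try:
        auc = roc_auc(y_test, scores)
    except UndefinedMetricError:
        auc = float("nan")
    return replace(m, auc=auc), scores


def _train_on(dataset: LabeledDataset, idx: np.ndarray, config: ModelConfig,
              variant: str, seed: int) -> TrainedModel:
    records, labels = dataset.subset(idx)
    split_config = replace(config, seed=seed)
    subset = LabeledDataset(records=records, labels=labels)
    return train(build_variant(variant, split_config), subset, split_config)


def stratified_fold_indices(labels: np.ndarray, k: int, seed: int,
                            stratified: bool = True
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train, test) index pairs for k disjoint, exhaustive folds."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if stratified:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < k:
            raise TrainingError(
                f"stratified {k}-fold needs >= {k} samples per class; "
                f"have {counts.tolist()}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(labels.size), labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(labels.size))]


def kfold_cv(dataset: LabeledDataset, config: ModelConfig | None = None,
             k: int = 5, seed: int = 0, variant: str = "full",
             stratified: bool = True, threshold: float = 0.5
             ) -> ProtocolResult:
    """Stratified k-fold cross-validation (default five folds).

    The dataset is partitioned into k folds by ``seed``; each fold serves
    once as the test set for a model trained on the remaining k−1 folds.
    Per-fold metrics, their mean ± sd, and the pooled out-of-fold scores
    (for a pooled ROC) are returned.
    """
    config = config or ModelConfig()
    folds = stratified_fold_indices(dataset.labels, k, seed, stratified)
    per_split: list[MetricSet] = []
    descriptors: list[dict] = []
    pooled_scores = np.empty(len(dataset))
    pooled_mask = np.zeros(len(dataset), dtype=bool)
    for fold, (train_idx, test_idx) in enumerate(folds):
        trained = _train_on(dataset, train_idx, config, variant,
                            seed=(seed + fold) % (2 ** 31))
        m, scores = _evaluate_split(trained, dataset, test_idx, threshold)
        pooled_scores[test_idx] = scores
        pooled_mask[test_idx] = True
        per_split.append(m)
        descriptors.append({"fold": fold, "test_size": int(test_idx.size)})
    assert pooled_mask.all(), "folds must cover every sample exactly once"
    return ProtocolResult(
        protocol=f"{k}-fold-cv",
        per_split=per_split,
        split_descriptors=descriptors,
        pooled_labels=dataset.labels.copy(),
        pooled_scores=pooled_scores,
    )


def repeated_holdout(dataset: LabeledDataset,
                     config: ModelConfig | None = None,
                     test_fraction: float = 0.1, repeats: int = 10,
                     seed: int = 0, variant: str = "full",
                     threshold: float = 0.5) -> ProtocolResult:
    """Repeated random hold-out: shuffle, test on ``test_fraction``, repeat.

    Each repeat reshuffles the whole dataset with a fresh sub-seed and holds
    out ``test_fraction`` of it (unstratified, as a plain random split); a
    split that misses a class entirely is redrawn with the next sub-seed and
    the redraw recorded in the split descriptor.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    config = config or ModelConfig()
    n = len(dataset)
    n_test = max(1, int(round(test_fraction * n)))
    per_split: list[MetricSet] = []
    descriptors: list[dict] = []
    pooled_labels: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    draw = 0
    for repeat in range(repeats):
        while True:  # redraw until the test split contains both classes
            sub_seed = (seed + draw) % (2 ** 31)
            draw += 1
            order = np.random.default_rng(sub_seed).permutation(n)
            test_idx, train_idx = order[:n_test], order[n_test:]
            test_classes = np.unique(dataset.labels[test_idx])
            train_classes = np.unique(dataset.labels[train_idx])
            if test_classes.size == 2 and train_classes.size == 2:
                break
        trained = _train_on(dataset, train_idx, config, variant, seed=sub_seed)
        m, scores = _evaluate_split(trained, dataset, test_idx, threshold)
        per_split.append(m)
        descriptors.append({"repeat": repeat, "sub_seed": sub_seed,
                            "test_size": int(test_idx.size),
                            "redraws": draw - 1 - repeat})
        pooled_labels.append(dataset.labels[test_idx])
        pooled_scores.append(scores)
    return ProtocolResult(
        protocol="repeated-holdout",
        per_split=per_split,
        split_descriptors=descriptors,
        pooled_labels=np.concatenate(pooled_labels),
        pooled_scores=np.concatenate(pooled_scores),
    )


def compare_ttest(metric_runs_a: Sequence[float],
                  metric_runs_b: Sequence[float]) -> float:
    """Two-sided two-sample Welch t-test p-value on per-repetition metrics.

    Two constant, equal samples are reported as p = 1 (no evidence of a
    difference) rather than the NaN the raw statistic would give.
    """
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two runs")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
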