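"""The four-metric report (Sn, Sp, Acc, MCC), jackknife/k-fold protocols, ROC.

Metrics follow the intuitive "miss-count" formulation: with N+ true sites of
which N-+ are missed, and N- non-sites of which N+- are falsely called,

    Sn  = 1 - N-+/N+
    Sp  = 1 - N+-/N-
    Acc = 1 - (N-+ + N+-)/(N+ + N-)
    MCC = [1 - (N-+/N+ + N+-/N-)] /
          sqrt[(1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-)]

which is algebraically identical to the standard Matthews coefficient on the
corresponding confusion matrix.  When an MCC denominator factor vanishes
(all predictions in one class) MCC is reported as 0 with a warning.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import ForestConfig, predict_scores, train_forest
from .coupling import encode_dataset, encode_windows, fit_model
from .peptides import AnnotatedProtein, BenchmarkDataset, ValidationError, build_benchmark

PROTOCOLS = ("strict", "paper_style")


@dataclass(frozen=True)
class ConfusionCounts:
    """Miss-count bookkeeping: totals per class and the two error counts."""

    n_pos: int      # N+  : true sites investigated
    n_neg: int      # N-  : non-sites investigated
    miss_pos: int   # N-+ : true sites predicted as non-sites
    false_pos: int  # N+- : non-sites predicted as sites

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValidationError("class totals must be nonnegative")
        if not 0 <= self.miss_pos <= self.n_pos:
            raise ValidationError(f"miss_pos={self.miss_pos} out of [0, {self.n_pos}]")
        if not 0 <= self.false_pos <= self.n_neg:
            raise ValidationError(f"false_pos={self.false_pos} out of [0, {self.n_neg}]")

    @property
    def tp(self) -> int:
        return self.n_pos - self.miss_pos

    @property
    def tn(self) -> int:
        return self.n_neg - self.false_pos


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts, the four metrics, and (optionally) the ROC curve."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    roc: np.ndarray | None = None   # (n_points, 2) columns: FPR, TPR
    auc: float | None = None
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "n_pos": self.counts.n_pos, "n_neg": self.counts.n_neg,
            "miss_pos": self.counts.miss_pos, "false_pos": self.counts.false_pos,
            "acc_percent": 100.0 * self.acc, "mcc": self.mcc,
            "sn_percent": 100.0 * self.sn, "sp_percent": 100.0 * self.sp,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def format_table(self) -> str:
        """One-row table in the conventional layout (Acc %, MCC, Sn %, Sp %)."""
        header = "Acc (%)\tMCC\tSn (%)\tSp (%)"
        row = (f"{100 * self.acc:.2f}\t{self.mcc:.2f}\t"
               f"{100 * self.sn:.2f}\t{100 * self.sp:.2f}")
        return header + "\n" + row

    def write_roc_tsv(self, path: str | Path) -> None:
        if self.roc is None:
            raise ValidationError("report carries no ROC curve")
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate Sn/Sp/Acc/MCC from confusion counts (no ROC attached)."""
    if counts.n_pos == 0:
        raise ValidationError("sensitivity undefined: no positive samples")
    if counts.n_neg == 0:
        raise ValidationError("specificity undefined: no negative samples")
    m, f = counts.miss_pos, counts.false_pos
    npos, nneg = counts.n_pos, counts.n_neg
    sn = 1.0 - m / npos
    sp = 1.0 - f / nneg
    acc = 1.0 - (m + f) / (npos + nneg)
    denom_sq = (1.0 + (f - m) / npos) * (1.0 + (m - f) / nneg)
    num = 1.0 - (m / npos + f / nneg)
    if denom_sq <= 0:
        # all predictions fall in one class; the coefficient is conventionally 0
        warnings.warn("MCC denominator is zero (single-class predictions); reporting 0")
        mcc = 0.0
    else:
        mcc = num / math.sqrt(denom_sq)
    return MetricsReport(counts=counts, sn=sn, sp=sp, acc=acc, mcc=mcc)


def counts_from_predictions(labels: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    return ConfusionCounts(
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
        miss_pos=int(((labels == 1) & (predicted == 0)).sum()),
        false_pos=int(((labels == 0) & (predicted == 1)).sum()),
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all distinct thresholds, and trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney statistic (fraction of
    concordant positive/negative score pairs, ties counted one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels).tolist()) != {0, 1}:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def _report_from_scores(scores: np.ndarray, labels: np.ndarray,
                        threshold: float) -> MetricsReport:
    predicted = scores >= threshold
    counts = counts_from_predictions(labels, predicted)
    base = compute_metrics(counts)
    roc, auc = roc_curve(scores, labels)
    return MetricsReport(counts=base.counts, sn=base.sn, sp=base.sp, acc=base.acc,
                         mcc=base.mcc, roc=roc, auc=auc,
                         scores=scores.copy(), labels=labels.copy())


def _dataset_windows(dataset: BenchmarkDataset) -> tuple[list[str], np.ndarray]:
    windows = [s.window for s in dataset.positives] + [s.window for s in dataset.negatives]
    labels = np.concatenate([
        np.ones(len(dataset.positives), dtype=int),
        np.zeros(len(dataset.negatives), dtype=int),
    ])
    return windows, labels


def _subset_dataset(dataset: BenchmarkDataset, idx: np.ndarray) -> BenchmarkDataset:
    all_samples = list(dataset.positives) + list(dataset.negatives)
    chosen = [all_samples[i] for i in idx]
    return BenchmarkDataset(
        target=dataset.target, xi=dataset.xi,
        positives=tuple(s for s in chosen if s.is_positive),
        negatives=tuple(s for s in chosen if not s.is_positive),
    )


def _cv_scores(dataset: BenchmarkDataset, folds: Sequence[tuple[np.ndarray, np.ndarray]],
               forest_config: ForestConfig, protocol: str, smoothing) -> np.ndarray:
    """Score every sample out-of-fold under the given protocol.

    strict: coupling tables AND forest are refit on each fold's training part.
    paper_style: coupling tables are fitted once on the full dataset; only the
    forest is refit per fold.
    """
    if protocol not in PROTOCOLS:
        raise ValidationError(f"protocol must be one of {PROTOCOLS}, got {protocol!r}")
    windows, labels = _dataset_windows(dataset)
    n = len(windows)
    scores = np.full(n, np.nan)
    if protocol == "paper_style":
        model = fit_model(dataset, smoothing)
        X_all, _ = encode_dataset(dataset, model)
        for train_idx, test_idx in folds:
            forest = train_forest(X_all[train_idx], labels[train_idx], forest_config)
            scores[test_idx] = predict_scores(forest, X_all[test_idx])
    else:
        for train_idx, test_idx in folds:
            fold_model = fit_model(_subset_dataset(dataset, train_idx), smoothing)
            X_train = encode_windows([windows[i] for i in train_idx], fold_model)
            X_test = encode_windows([windows[i] for i in test_idx], fold_model)
            forest = train_forest(X_train, labels[train_idx], forest_config)
            scores[test_idx] = predict_scores(forest, X_test)
    assert not np.isnan(scores).any()
    return scores


def _check_dataset(dataset: BenchmarkDataset) -> None:
    if len(dataset.positives) < 2 or len(dataset.negatives) < 2:
        raise ValidationError(
            "cross-validation needs at least 2 samples in each subset "
            f"(got {len(dataset.positives)} positives, {len(dataset.negatives)} negatives)"
        )


def _loo_folds(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    all_idx = np.arange(n)
    return [(np.delete(all_idx, i), np.array([i])) for i in range(n)]


def jackknife(dataset: BenchmarkDataset, forest_config: ForestConfig | None = None,
              protocol: str = "strict", smoothing="none",
              threshold: float = 0.5) -> MetricsReport:
    """Leave-one-out test: each sample is scored by a model trained on the rest."""
    _check_dataset(dataset)
    forest_config = forest_config or ForestConfig()
    _, labels = _dataset_windows(dataset)
    scores = _cv_scores(dataset, _loo_folds(len(labels)), forest_config,
                        protocol, smoothing)
    return _report_from_scores(scores, labels, threshold)


def kfold(dataset: BenchmarkDataset, k: int, forest_config: ForestConfig | None = None,
          protocol: str = "strict", smoothing="none", threshold: float = 0.5,
          seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation; k equal to the dataset size is the
    jackknife (identical folds)."""
    _check_dataset(dataset)
    forest_config = forest_config or ForestConfig()
    _, labels = _dataset_windows(dataset)
    n = len(labels)
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    if k == n:
        folds = _loo_folds(n)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(np.zeros((n, 1)), labels)]
    scores = _cv_scores(dataset, folds, forest_config, protocol, smoothing)
    return _report_from_scores(scores, labels, threshold)


def select_window_size(proteins: Sequence[AnnotatedProtein], target: str,
                       xi_values: Sequence[int],
                       forest_config: ForestConfig | None = None,
                       protocol: str = "strict", smoothing="none",
                       threshold: float = 0.5, k: int | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Evaluate one benchmark per window half-width and tabulate the metrics.

    ``k=None`` runs the jackknife; an integer runs stratified k-fold.
    Returns a DataFrame indexed by xi with columns n_pos, n_neg, acc, mcc,
    sn, sp, auc.
    """
    if not xi_values:
        raise ValidationError("xi_values must be non-empty")
    rows = []
    for xi in xi_values:
        dataset = build_benchmark(proteins, target, xi)
        if k is None:
            report = jackknife(dataset, forest_config, protocol, smoothing, threshold)
        else:
            report = kfold(dataset, k, forest_config, protocol, smoothing,
                           threshold, seed)
        rows.append({
            "xi": xi,
            "n_pos": report.counts.n_pos, "n_neg": report.counts.n_neg,
            "acc": report.acc, "mcc": report.mcc,
            "sn": report.sn, "sp": report.sp, "auc": report.auc,
        })
    return pd.DataFrame(rows).set_index("xi")
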