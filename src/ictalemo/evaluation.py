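"""Confusion-matrix metrics and randomized sub-sampling cross-validation.

The metrics are those the selection objective and the final report
consume, with ictal as the positive class:

    CA  = (TN + TP) / (TP + TN + FP + FN) * 100
    Er  = 100 - CA
    SN  = TP / (TP + FN) * 100
    SP  = TN / (TN + FP) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A degenerate MCC denominator yields NaN (an explicit undefined flag),
never a silent 0 — trivial all-one-class predictors must not be rewarded.

Cross-validation is Monte-Carlo (randomized sub-sampling): 10 stratified
half-splits by default, the GRNN refitted on each training half with
scaling statistics from that half only, and the mean error rate
Er = 100 - mean CA returned. Splits are drawn deterministically from the
given seed, so every feature mask scored with the same seed is scored on
identical splits — the selection objective is noise-free between masks.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from ictalemo import grnn
from ictalemo.feature_extraction import FeatureMatrix
from ictalemo.signal_io import Label


@dataclass
class ConfusionCounts:
    """Binary confusion counts; ictal is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """CA, SN, SP in percent; MCC in [-1, 1] (NaN when undefined); Er = 100 - CA; CT in s."""

    ca: float
    sn: float
    sp: float
    mcc: float
    er: float
    ct: float

    def as_dict(self) -> dict[str, float]:
        return {"CA": self.ca, "SN": self.sn, "SP": self.sp, "MCC": self.mcc, "Er": self.er, "CT": self.ct}


def _to01(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.intp)
    for i, v in enumerate(labels):
        if isinstance(v, Label):
            out[i] = 1 if v is Label.ICTAL else 0
        else:
            iv = int(v)
            if iv not in (0, 1):
                raise ValueError(f"labels must be binary, got {v!r}")
            out[i] = iv
    return out


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN over aligned binary label sequences."""
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    if len(true_labels) != len(predicted_labels):
        raise ValueError(f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted")
    t = _to01(true_labels)
    p = _to01(predicted_labels)
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(counts: ConfusionCounts, elapsed: float = 0.0) -> MetricReport:
    """Apply the metric formulas verbatim; degenerate ratios become NaN flags."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    ca = (tn + tp) / total * 100.0
    sn = tp / (fn + tp) * 100.0 if (fn + tp) else math.nan
    sp = tn / (fp + tn) * 100.0 if (fp + tn) else math.nan
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else math.nan
    return MetricReport(ca=ca, sn=sn, sp=sp, mcc=mcc, er=100.0 - ca, ct=elapsed)


def _stratified_half_split(labels01: np.ndarray, rng: np.random.Generator, train_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """One stratified random split; class proportions preserved within +-1 sample."""
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in (0, 1):
        members = np.where(labels01 == cls)[0]
        perm = rng.permutation(members)
        k = int(round(len(members) * train_fraction))
        k = min(max(k, 1), len(members) - 1)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def random_subsample_cv(
    fm: FeatureMatrix | np.ndarray,
    mask: np.ndarray | None = None,
    n_iter: int = 10,
    sigma: float = grnn.DEFAULT_SIGMA,
    seed: int = 0,
    labels=None,
    train_fraction: float = 0.5,
) -> float:
    """Mean error rate (percent) over ``n_iter`` randomized stratified half-splits.

    ``fm`` is a FeatureMatrix (labels carried inside) or a plain array
    with ``labels`` given separately; ``mask`` restricts to the selected
    feature columns. Per iteration the GRNN is fitted on the training
    half — its z-scoring statistics come from that half only — and
    accuracy is measured on the testing half. Deterministic given seed.
    """
    if isinstance(fm, FeatureMatrix):
        values = fm.values
        labels01 = fm.labels01()
    else:
        values = np.asarray(fm, dtype=np.float64)
        if labels is None:
            raise ValueError("labels required when fm is a plain array")
        labels01 = _to01(labels)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if labels01.min() == labels01.max():
        raise ValueError("both classes must be present for cross-validation")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty feature mask")
        values = values[:, mask]
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    for it in range(n_iter):
        tr, te = _stratified_half_split(labels01, rng, train_fraction)
        model = grnn.fit(values[tr], labels01[tr], sigma=sigma)
        pred = grnn.classify(model, values[te])
        accs[it] = np.mean(pred == labels01[te]) * 100.0
    return float(100.0 - accs.mean())


def holdout_report(
    train_values: np.ndarray,
    train_labels01: np.ndarray,
    test_values: np.ndarray,
    test_labels01: np.ndarray,
    sigma: float,
) -> MetricReport:
    """Fit on the training partition, classify the held-out partition, report metrics.

    CT is the wall-clock time of the classification call only.
    """
    model = grnn.fit(train_values, train_labels01, sigma=sigma)
    t0 = time.perf_counter()
    pred = grnn.classify(model, test_values)
    elapsed = time.perf_counter() - t0
    return metrics(confusion(test_labels01, pred), elapsed)
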