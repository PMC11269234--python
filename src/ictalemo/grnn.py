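"""Generalized regression neural network (GRNN).

A one-pass, memory-based kernel regressor: training consists of storing
the (scaled) training patterns X_i and their targets Y_i; prediction is
the Gaussian-kernel-weighted average

    Yhat(X) = sum_i Y_i exp(-d_i^2 / (2 sigma^2)) / sum_i exp(-d_i^2 / (2 sigma^2))

with d_i^2 the squared Euclidean distance between the query and pattern i
in z-scored feature space. The smoothing parameter sigma controls the
kernel width: as sigma -> 0 the predictor converges to 1-nearest-neighbor
and as sigma -> infinity to the target mean. With non-ictal coded 0 and
ictal coded 1 the prediction behaves as a posterior-like score, and a
0.5 threshold yields the class decision.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ictalemo.signal_io import Label

SIGMA_GRID = (0.05, 0.1, 0.2, 0.5, 1.0)
DEFAULT_SIGMA = 0.5


@dataclass
class GRNNModel:
    """Stored training patterns, 0/1 targets, kernel width and feature scaler."""

    patterns: np.ndarray  # n x d, already z-scored
    targets: np.ndarray  # n, values in [0, 1]
    sigma: float
    center: np.ndarray  # d, training-column means
    spread: np.ndarray  # d, training-column standard deviations (degenerate -> 1)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_features(self) -> int:
        return self.patterns.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(path, patterns=self.patterns, targets=self.targets, sigma=self.sigma, center=self.center, spread=self.spread)

    @classmethod
    def load(cls, path: str | Path) -> "GRNNModel":
        with np.load(path) as z:
            return cls(patterns=z["patterns"], targets=z["targets"], sigma=float(z["sigma"]), center=z["center"], spread=z["spread"])


def _coerce_targets(y: Sequence) -> np.ndarray:
    out = np.empty(len(y), dtype=np.float64)
    for i, v in enumerate(y):
        if isinstance(v, Label):
            out[i] = 1.0 if v is Label.ICTAL else 0.0
        else:
            out[i] = float(v)
    if not np.isin(out, (0.0, 1.0)).all():
        raise ValueError("targets must be binary (0/1 or ictal/non_ictal labels)")
    return out


def fit(X: np.ndarray, y: Sequence, sigma: float = DEFAULT_SIGMA) -> GRNNModel:
    """Store z-scored training patterns and their 0/1 targets.

    There is no iterative training: fitting is a single pass that computes
    the per-feature center/spread and memorizes the scaled patterns.
    Constant (zero-spread) features get unit spread so they contribute no
    distance rather than NaNs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.size == 0:
        raise ValueError("empty training matrix")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    targets = _coerce_targets(y)
    if targets.size != X.shape[0]:
        raise ValueError("pattern/target length mismatch")
    center = X.mean(axis=0)
    spread = X.std(axis=0, ddof=0)
    spread = np.where(spread > 0, spread, 1.0)
    return GRNNModel(patterns=(X - center) / spread, targets=targets, sigma=sigma, center=center, spread=spread)


def predict(model: GRNNModel, X: np.ndarray) -> np.ndarray:
    """Kernel-weighted mean target for each query row; bounded by the target range.

    Exponents are shifted by their row maximum before exponentiation so
    large distances or tiny sigma never underflow into 0/0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(f"query dimension {X.shape[1]} != training dimension {model.n_features}")
    q = (X - model.center) / model.spread
    d2 = cdist(q, model.patterns, metric="sqeuclidean")
    expo = -d2 / (2.0 * model.sigma**2)
    expo -= expo.max(axis=1, keepdims=True)
    w = np.exp(expo)
    out = w @ model.targets / w.sum(axis=1)
    # float summation can overshoot the exact weighted-mean bounds by ~1 ulp
    return np.clip(out, model.targets.min(), model.targets.max())


def classify(model: GRNNModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold the regression score into 0/1 class codes (tie at threshold -> ictal)."""
    return (predict(model, X) >= threshold).astype(np.intp)


def predict_timed(model: GRNNModel, X: np.ndarray, threshold: float = 0.5) -> tuple[np.ndarray, float]:
    """Classify and report the wall-clock seconds of the classification call (CT)."""
    t0 = time.perf_counter()
    pred = classify(model, X, threshold)
    return pred, time.perf_counter() - t0


def grid_search_sigma(
    X: np.ndarray,
    y: Sequence,
    grid: Sequence[float] = SIGMA_GRID,
    n_iter: int = 5,
    seed: int = 0,
) -> float:
    """Pick sigma from ``grid`` by randomized sub-sampling CV on the training set only.

    Each candidate is scored by mean error over ``n_iter`` stratified
    half-splits of (X, y); ties favor the smaller sigma. The data passed
    here must be training data — the held-out partition never
    participates in sigma selection.
    """
    from ictalemo.evaluation import _stratified_half_split

    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    targets = _coerce_targets(y)
    rng = np.random.default_rng(seed)
    splits = [_stratified_half_split(targets, rng) for _ in range(n_iter)]
    best_sigma, best_err = None, np.inf
    for s in grid:
        errs = []
        for tr, te in splits:
            model = fit(X[tr], targets[tr], sigma=s)
            errs.append(np.mean(classify(model, X[te]) != targets[te]))
        err = float(np.mean(errs))
        if err < best_err - 1e-12:
            best_sigma, best_err = s, err
    assert best_sigma is not None
    return best_sigma
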