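"""Relief and ReliefF feature weighting, and per-channel weight aggregation.

Relief scores a feature by how well it separates randomly drawn samples
from their nearest neighbor of a different class (the "nearest miss")
relative to their nearest neighbor of the same class (the "nearest hit"):
features whose values differ more across classes than within gain weight.
ReliefF generalizes this to k neighbors and to more than two classes,
weighting each other class's miss term by its prior probability.

Conventions adopted here (the algorithm family leaves them open):
Manhattan distance on range-normalized features for the neighbor search,
matching the per-feature diff used in the weight update; nearest-neighbor
ties broken by lowest sample index; the feature range (max - min) is taken
from the data the weights are fit on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "ReliefConfig",
    "FeatureWeights",
    "diff",
    "relief_weights",
    "relieff_weights",
    "threshold_select",
    "channel_weights",
]


@dataclass
class ReliefConfig:
    """Sampling and neighborhood parameters.

    m_iter : number of sampled reference points; None = one deterministic
        full pass over all samples in index order.
    k : neighbor count for ReliefF; None = 10 clipped to (smallest class
        size - 1). An explicit k that a class cannot honor is an error.
    delta : weight threshold used by :func:`threshold_select`.
    sample_without_replacement : applies when m_iter is given.
    """

    m_iter: int | None = None
    k: int | None = None
    delta: float = 0.0
    seed: int = 0
    sample_without_replacement: bool = True

    def __post_init__(self) -> None:
        if self.m_iter is not None and self.m_iter < 1:
            raise ValueError("m_iter must be >= 1")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class FeatureWeights:
    """Per-column Relief/ReliefF weights, aligned to a FeatureMatrix."""

    w: np.ndarray
    column_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.column_index = [tuple(c) for c in self.column_index]
        if len(self.w) != len(self.column_index):
            raise ValueError("w and column_index must align")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")


def diff(
    value_a: float,
    value_b: float,
    feature_min: float = 0.0,
    feature_max: float = 1.0,
    is_discrete: bool = False,
) -> float:
    """Per-feature sample distance in [0, 1].

    Discrete features: 0 if equal else 1. Continuous features:
    |a - b| / (max - min); a degenerate range (max = min) contributes 0.
    """
    if feature_max < feature_min:
        raise ValueError("feature_max must be >= feature_min")
    if is_discrete:
        return 0.0 if value_a == value_b else 1.0
    rng = feature_max - feature_min
    if rng == 0:
        return 0.0
    return abs(value_a - value_b) / rng


def _as_xy(X, y):
    if isinstance(X, FeatureMatrix):
        cols = list(X.column_index)
        if y is None:
            y = X.labels
        X = X.values
    else:
        X = np.asarray(X, dtype=float)
        cols = [(f"col{j}", "f0") for j in range(X.shape[1])]
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y must align")
    return X, y, cols


def _normalize(X: np.ndarray) -> np.ndarray:
    """Range-normalize columns; zero-range columns map to all-zeros so they
    never contribute to distances or weights."""
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng == 0, 1.0, rng)
    Z = (X - lo) / safe
    Z[:, rng == 0] = 0.0
    return Z


def _sample_order(n: int, cfg: ReliefConfig) -> np.ndarray:
    if cfg.m_iter is None:
        return np.arange(n)
    rng = np.random.default_rng(cfg.seed)
    if cfg.sample_without_replacement:
        m = min(cfg.m_iter, n)
        return rng.permutation(n)[:m]
    return rng.integers(0, n, size=cfg.m_iter)


def _k_nearest(dist_row: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k candidates nearest by dist_row; distance ties go to
    the lowest sample index (candidates are pre-sorted by index and the
    sort is stable)."""
    order = np.argsort(dist_row[candidates], kind="stable")
    return candidates[order[:k]]


def relief_weights(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    cfg: ReliefConfig | None = None,
) -> FeatureWeights:
    """Original two-class Relief: single nearest hit and miss per sample.

    For each sampled point the weight of every feature is decreased by its
    diff to the nearest hit and increased by its diff to the nearest miss,
    each divided by the number of sampled points.
    """
    cfg = cfg or ReliefConfig()
    X, y, cols = _as_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"Relief requires exactly 2 classes, got {len(classes)}")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 samples")

    Z = _normalize(X)
    D = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)  # Manhattan
    order = _sample_order(len(y), cfg)
    m = len(order)
    w = np.zeros(Z.shape[1])
    for i in order:
        same = np.flatnonzero((y == y[i]) & (np.arange(len(y)) != i))
        other = np.flatnonzero(y != y[i])
        hit = _k_nearest(D[i], same, 1)[0]
        miss = _k_nearest(D[i], other, 1)[0]
        w += (-np.abs(Z[i] - Z[hit]) + np.abs(Z[i] - Z[miss])) / m
    return FeatureWeights(w=w, column_index=cols)


def relieff_weights(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    cfg: ReliefConfig | None = None,
) -> FeatureWeights:
    """ReliefF: k nearest hits, and k nearest misses per other class with
    the miss term weighted by p(C) / (1 - p(class(sample))).

    All terms are averaged by 1/(m*k); class priors are the empirical
    class proportions.
    """
    cfg = cfg or ReliefConfig()
    X, y, cols = _as_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least 2 classes")
    if cfg.k is None:
        k = max(1, min(10, int(counts.min()) - 1))
    else:
        k = cfg.k
        for c, n_c in zip(classes, counts):
            if n_c < k + 1:
                raise ValueError(
                    f"class {c!r} has {n_c} samples; k={k} needs at least {k + 1}"
                )
    priors = {c: n_c / len(y) for c, n_c in zip(classes, counts)}

    Z = _normalize(X)
    D = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    order = _sample_order(len(y), cfg)
    m = len(order)
    w = np.zeros(Z.shape[1])
    for i in order:
        same = np.flatnonzero((y == y[i]) & (np.arange(len(y)) != i))
        hits = _k_nearest(D[i], same, k)
        w -= np.abs(Z[i] - Z[hits]).sum(axis=0) / (m * k)
        for c in classes:
            if c == y[i]:
                continue
            cand = np.flatnonzero(y == c)
            misses = _k_nearest(D[i], cand, k)
            scale = priors[c] / (1.0 - priors[y[i]])
            w += scale * np.abs(Z[i] - Z[misses]).sum(axis=0) / (m * k)
    return FeatureWeights(w=w, column_index=cols)


def threshold_select(w: FeatureWeights, delta: float) -> list[int]:
    """Column indices with weight >= delta, original order preserved."""
    selected = [j for j, wj in enumerate(w.w) if wj >= delta]
    if not selected:
        warnings.warn(f"threshold_select: no feature weight reaches delta={delta}")
    return selected


def channel_weights(w: FeatureWeights) -> tuple[list[str], np.ndarray]:
    """Aggregate per-(channel, feature) weights to per-channel weights by
    the arithmetic mean over each channel's features.

    Requires every channel to carry the same feature set (the mean is over
    a common feature count b).
    """
    channels: dict[str, list[float]] = {}
    feats: dict[str, set[str]] = {}
    for (ch, f), wj in zip(w.column_index, w.w):
        channels.setdefault(ch, []).append(wj)
        feats.setdefault(ch, set()).add(f)
    sets = {frozenset(s) for s in feats.values()}
    if len(sets) != 1:
        raise ValueError("ragged coverage: channels carry different feature sets")
    labels = list(channels)
    means = np.array([np.mean(channels[ch]) for ch in labels])
    return labels, means
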