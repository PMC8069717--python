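"""Common-channel selection across subjects.

Two aggregation schemes reduce per-subject, per-(channel, feature) ReliefF
weights to a single cross-subject channel ranking:

* weight addition — each subject's per-channel weights (feature means) are
  min-max normalized across channels, then summed over subjects;
* accuracy weighting — each (channel, feature, subject) weight is
  multiplied by that single channel-feature's classification accuracy
  (SRDA under stratified cross-validation) and the products summed over
  features and subjects.

The top half of the ranking (8 of 16 channels in the reference montage)
becomes the common channel set used for every subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix
from .relieff import ReliefConfig, channel_weights, relieff_weights
from .srda import srda_fit, srda_predict

__all__ = [
    "ChannelWeightTable",
    "single_channel_accuracy",
    "build_channel_weight_table",
    "common_weights_addition",
    "common_weights_accuracy",
    "select_common_channels",
]


@dataclass
class ChannelWeightTable:
    """Per-subject ReliefF weights and single-channel accuracies.

    Arrays are (n_subjects, n_channels, n_features); accuracies in [0, 1].
    """

    weights: np.ndarray
    accuracies: np.ndarray
    channel_labels: list[str]
    subject_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.weights.shape != self.accuracies.shape:
            raise ValueError("weights and accuracies shapes must agree")
        if self.weights.ndim != 3:
            raise ValueError("expected (n_subjects, n_channels, n_features) arrays")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        s, c, f = self.weights.shape
        if (len(self.subject_ids), len(self.channel_labels), len(self.feature_names)) != (s, c, f):
            raise ValueError("label lists must match array shape")


def single_channel_accuracy(
    X: FeatureMatrix,
    channel: str,
    feature: str,
    cv_folds: int = 5,
    seed: int = 0,
    reg_alpha: float = 0.01,
) -> float:
    """Mean SRDA accuracy of the single (channel, feature) column under
    seeded stratified k-fold cross-validation."""
    col = X.column(channel, feature)[:, None]
    y = X.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(col, y):
        model = srda_fit(col[tr], y[tr], reg_alpha=reg_alpha)
        accs.append(float(np.mean(srda_predict(model, col[te]) == y[te])))
    return float(np.mean(accs))


def build_channel_weight_table(
    X: FeatureMatrix,
    relief_cfg: ReliefConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    reg_alpha: float = 0.01,
) -> ChannelWeightTable:
    """Run ReliefF and single-channel accuracy estimation per subject.

    ``X`` holds all subjects' epochs; subjects are separated by
    ``X.subject_ids`` and each subject's weights/accuracies are computed on
    that subject's rows only.
    """
    subjects = list(dict.fromkeys(str(s) for s in X.subject_ids))
    chans = X.channels
    feats = X.feature_names
    W = np.zeros((len(subjects), len(chans), len(feats)))
    A = np.zeros_like(W)
    for si, sid in enumerate(subjects):
        sub = X.subset(np.asarray([str(s) == sid for s in X.subject_ids]))
        fw = relieff_weights(sub, cfg=relief_cfg)
        wmap = dict(zip(fw.column_index, fw.w))
        for ci, ch in enumerate(chans):
            for fi, f in enumerate(feats):
                W[si, ci, fi] = wmap[(ch, f)]
                A[si, ci, fi] = single_channel_accuracy(
                    sub, ch, f, cv_folds=cv_folds, seed=seed, reg_alpha=reg_alpha
                )
    return ChannelWeightTable(
        weights=W,
        accuracies=A,
        channel_labels=chans,
        subject_ids=subjects,
        feature_names=feats,
    )


def common_weights_addition(
    table: ChannelWeightTable, normalize: str = "minmax"
) -> np.ndarray:
    """Weight-addition scheme: per subject, mean weights over features per
    channel, normalize across that subject's channels, sum over subjects.

    ``normalize`` is "minmax" (default, weights mapped to [0, 1]) or "sum"
    (weights scaled to sum to one). A subject whose channel weights are all
    equal contributes a constant vector (0.5 under minmax) with a warning.
    """
    if table.weights.shape[0] < 1:
        raise ValueError("need at least one subject")
    per_channel = table.weights.mean(axis=2)  # (subjects, channels)
    out = np.zeros(per_channel.shape[1])
    for si, wvec in enumerate(per_channel):
        rng = wvec.max() - wvec.min()
        if normalize == "minmax":
            if rng == 0:
                warnings.warn(
                    f"subject {table.subject_ids[si]}: all channel weights equal; "
                    "normalized vector set to 0.5"
                )
                norm = np.full_like(wvec, 0.5)
            else:
                norm = (wvec - wvec.min()) / rng
        elif normalize == "sum":
            total = wvec.sum()
            norm = wvec / total if total != 0 else np.full_like(wvec, 1 / len(wvec))
        else:
            raise ValueError(f"unknown normalize mode {normalize!r}")
        out += norm
    return out


def common_weights_accuracy(table: ChannelWeightTable) -> np.ndarray:
    """Accuracy-weighted scheme: sum over subjects and features of
    weight x single-channel accuracy."""
    return np.einsum("scf,scf->c", table.weights, table.accuracies)


def select_common_channels(
    weights: np.ndarray, channel_labels: list[str], n_keep: int | None = None
) -> list[str]:
    """Channels sorted by weight descending (ties keep original channel
    order), truncated to ``n_keep`` (default: half, rounded down)."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(channel_labels):
        raise ValueError("weights and channel_labels must align")
    if n_keep is None:
        n_keep = len(channel_labels) // 2
    if n_keep > len(channel_labels):
        raise ValueError("n_keep exceeds channel count")
    order = np.argsort(-weights, kind="stable")
    return [channel_labels[i] for i in order[:n_keep]]
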