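"""Per-epoch, per-channel EEG features.

Five features are extracted from every channel of every epoch: log band
power (Welch PSD integrated over the four canonical EEG bands) and sample
entropy. With 16 channels this yields the 80-column feature table the
fusion stage consumes.

Band edges (Hz): delta 0.5-4, theta 4-8, alpha 8-12, beta 12-30. Band
power integrates the Welch PSD over the closed interval [lo, hi] by the
trapezoid rule, so adjacent bands share each edge bin at half weight and
no spectral mass is counted twice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochSet

__all__ = [
    "BANDS",
    "FEATURE_NAMES",
    "FeatureMatrix",
    "band_power",
    "band_psd",
    "sample_entropy",
    "extract_features",
]

#: canonical EEG bands, Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: fixed feature (column) order within each channel
FEATURE_NAMES: tuple[str, ...] = (
    "psd_beta",
    "psd_alpha",
    "psd_theta",
    "psd_delta",
    "sample_entropy",
)

_PSD_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Epochs x (channel, feature) table; the unit ReliefF operates on."""

    values: np.ndarray  # (n_epochs, n_columns)
    column_index: list[tuple[str, str]]  # (channel_label, feature_name)
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        self.column_index = [tuple(c) for c in self.column_index]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_epochs, n_columns)")
        if len(self.column_index) != self.values.shape[1]:
            raise ValueError("column_index length must equal n_columns")
        if len(set(self.column_index)) != len(self.column_index):
            raise ValueError("duplicate (channel, feature) column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for ch, _ in self.column_index:
            seen.setdefault(ch, None)
        return list(seen)

    @property
    def feature_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, f in self.column_index:
            seen.setdefault(f, None)
        return list(seen)

    def column(self, channel: str, feature: str) -> np.ndarray:
        try:
            j = self.column_index.index((channel, feature))
        except ValueError as exc:
            raise KeyError(f"no column ({channel!r}, {feature!r})") from exc
        return self.values[:, j]

    def select_channels(self, channels: list[str]) -> "FeatureMatrix":
        """Restrict to the given channels (order preserved as given)."""
        cols = [j for ch in channels for j, (c, _) in enumerate(self.column_index) if c == ch]
        if not cols:
            raise KeyError(f"none of {channels} present")
        return FeatureMatrix(
            values=self.values[:, cols],
            column_index=[self.column_index[j] for j in cols],
            labels=self.labels,
            subject_ids=self.subject_ids,
        )

    def select_features(self, features: list[str]) -> "FeatureMatrix":
        cols = [j for j, (_, f) in enumerate(self.column_index) if f in features]
        if not cols:
            raise KeyError(f"none of {features} present")
        return FeatureMatrix(
            values=self.values[:, cols],
            column_index=[self.column_index[j] for j in cols],
            labels=self.labels,
            subject_ids=self.subject_ids,
        )

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        """Row subset (epochs) by boolean mask or index array."""
        return FeatureMatrix(
            values=self.values[mask],
            column_index=list(self.column_index),
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
        )

    def save(self, path: str | Path) -> None:
        """CSV with a two-row (channel, feature) header + JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(
            self.values, columns=pd.MultiIndex.from_tuples(self.column_index)
        )
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "labels": self.labels.tolist(),
                    "subject_ids": [str(s) for s in self.subject_ids],
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, header=[0, 1])
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            values=df.to_numpy(),
            column_index=[tuple(c) for c in df.columns],
            labels=np.array(meta["labels"]),
            subject_ids=np.array(meta["subject_ids"]),
        )


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

def _welch(series: np.ndarray, fs: float, nperseg: int | None = None):
    """Welch PSD with the package defaults: Hamming window, segments of
    min(len, fs) samples, 50% overlap, linear detrend."""
    n = series.shape[-1]
    if nperseg is None:
        nperseg = min(n, int(round(fs)))
    return sps.welch(
        series,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
        axis=-1,
    )


def band_power(
    series: np.ndarray, fs: float, band: tuple[float, float], nperseg: int | None = None
) -> np.ndarray:
    """Welch PSD integrated (trapezoid) over ``band`` = [f_lo, f_hi].

    ``series`` may carry leading batch dimensions; integration is along the
    last axis. Returns raw power (not log-transformed).
    """
    f_lo, f_hi = band
    if f_hi > fs / 2 + 1e-9:
        raise ValueError(f"band edge {f_hi} Hz exceeds Nyquist {fs / 2} Hz")
    if f_lo >= f_hi:
        raise ValueError(f"empty band [{f_lo}, {f_hi})")
    freqs, psd = _welch(np.asarray(series, dtype=float), fs, nperseg)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if mask.sum() < 2:
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz covers <2 Welch frequency bins")
    return np.trapezoid(psd[..., mask], freqs[mask], axis=-1)


def band_psd(
    series: np.ndarray, fs: float, band: tuple[float, float], nperseg: int | None = None
) -> float | np.ndarray:
    """Log band power: log10(integrated PSD + eps), eps = 1e-12.

    The log stabilizes the heavy-tailed power scale before range
    normalization downstream; a constant series yields log10(eps).
    """
    return np.log10(band_power(series, fs, band, nperseg) + _PSD_EPS)


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

def _template_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Pairs of m- and (m+1)-length templates within Chebyshev distance r.

    The same n-m template start points are used at both lengths (each
    m-template has a matching (m+1)-extension), so a constant series gives
    A = B exactly.
    """
    n = len(x)
    nt = n - m  # template count at both lengths
    d = np.abs(x[:, None] - x[None, :])
    # D[i, j] = Chebyshev distance between m-length templates at i and j
    D = d[:nt, :nt].copy()
    for t in range(1, m):
        np.maximum(D, d[t : t + nt, t : t + nt], out=D)
    iu = np.triu_indices(nt, k=1)  # exclude self-matches
    b_mask = D[iu] <= r
    np.maximum(D, d[m : m + nt, m : m + nt], out=D)  # extend to length m+1
    a_mask = D[iu] <= r
    return int(a_mask.sum()), int(b_mask.sum())


try:  # compiled kernel: the O(n^2) pair scan dominates cohort extraction
    from numba import njit as _njit

    @_njit(cache=False)
    def _template_counts_jit(x, m, r):  # pragma: no cover - exercised via wrapper
        n = x.shape[0]
        nt = n - m
        a = 0
        b = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                dmax = 0.0
                for t in range(m):
                    d = abs(x[i + t] - x[j + t])
                    if d > dmax:
                        dmax = d
                        if dmax > r:
                            break
                if dmax <= r:
                    b += 1
                    d = abs(x[i + m] - x[j + m])
                    if d > dmax:
                        dmax = d
                    if dmax <= r:
                        a += 1
        return a, b

except ImportError:  # pragma: no cover
    _template_counts_jit = None


def _template_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    if _template_counts_jit is not None:
        a, b = _template_counts_jit(np.ascontiguousarray(x, dtype=np.float64), m, r)
        return int(a), int(b)
    return _template_counts_numpy(x, m, r)


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B) with Chebyshev distance, self-matches excluded.

    Parameters
    ----------
    series : 1-D signal.
    m : embedding dimension (template length).
    r : match tolerance, in the series' units. When None, 0.2 x the series
        standard deviation — the field-standard choice, and the one that
        makes the estimate invariant under affine maps of the series.

    A = 0 (no matches at length m+1) would give an infinite estimate; the
    finite surrogate -ln(1/(B+1)) is returned instead so downstream feature
    matrices stay finite.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < m + 2:
        raise ValueError(f"series of length {len(x)} too short for m={m}")
    if r is None:
        sd = float(x.std())
        if sd == 0:
            return 0.0  # constant series: every template matches
        r = 0.2 * sd
    if r <= 0:
        raise ValueError(f"tolerance r must be positive, got {r}")
    a, b = _template_counts(x, m, r)
    if b == 0:
        warnings.warn("sample_entropy: no m-length template matches; returning 0")
        return 0.0
    if a == 0:
        warnings.warn("sample_entropy: no (m+1)-length matches; finite surrogate used")
        return -np.log(1.0 / (b + 1))
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_features(
    epochs: EpochSet,
    feature_spec: list[str] | None = None,
    sampen_m: int = 2,
    sampen_r_factor: float = 0.2,
    welch_nperseg: int | None = None,
) -> FeatureMatrix:
    """Extract the requested features for every (epoch, channel).

    Column order is channels-major with the fixed feature order
    ``FEATURE_NAMES`` (beta, alpha, theta, delta band power, then sample
    entropy) within each channel.
    """
    if feature_spec is None:
        feature_spec = list(FEATURE_NAMES)
    if not feature_spec:
        raise ValueError("feature_spec must be non-empty")
    unknown = set(feature_spec) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    # fixed order regardless of the order given
    feats = [f for f in FEATURE_NAMES if f in feature_spec]

    n_ep, n_ch, _ = epochs.epochs.shape
    ch_labels = epochs.channel_labels or [f"ch{i}" for i in range(n_ch)]

    per_feature: dict[str, np.ndarray] = {}
    psd_feats = [f for f in feats if f.startswith("psd_")]
    if psd_feats:
        # one Welch pass, integrated over each requested band
        flat = epochs.epochs.reshape(n_ep * n_ch, -1)
        freqs, psd = _welch(flat, epochs.fs, welch_nperseg)
        for f in psd_feats:
            f_lo, f_hi = BANDS[f.removeprefix("psd_")]
            if f_hi > epochs.fs / 2 + 1e-9:
                raise ValueError(f"band edge {f_hi} Hz exceeds Nyquist")
            mask = (freqs >= f_lo) & (freqs <= f_hi)
            power = np.trapezoid(psd[..., mask], freqs[mask], axis=-1)
            per_feature[f] = np.log10(power + _PSD_EPS).reshape(n_ep, n_ch)
    if "sample_entropy" in feats:
        se = np.empty((n_ep, n_ch))
        for i in range(n_ep):
            for c in range(n_ch):
                x = epochs.epochs[i, c]
                sd = float(x.std())
                se[i, c] = sample_entropy(
                    x, m=sampen_m, r=sampen_r_factor * sd if sd > 0 else None
                )
        per_feature["sample_entropy"] = se

    columns = []
    values = np.empty((n_ep, n_ch * len(feats)))
    j = 0
    for c, ch in enumerate(ch_labels):
        for f in feats:
            values[:, j] = per_feature[f][:, c]
            columns.append((ch, f))
            j += 1
    return FeatureMatrix(
        values=values,
        column_index=columns,
        labels=epochs.labels,
        subject_ids=epochs.subject_ids,
    )
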