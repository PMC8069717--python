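"""Synthetic EEG cohort with known ground truth.

Each channel is a sum of band-limited Gaussian processes (white noise FIR
band-pass filtered into the delta/theta/alpha/beta bands) plus broadband
pink noise. In the fatigue state, a configured subset of "informative"
channels changes: band variances are scaled (by default alpha x1.8,
theta x1.5, beta x0.6 — the spectral shift reported for drowsiness) and
the broadband noise is AR(1)-smoothed more strongly, which lowers sample
entropy without changing total variance. Non-informative channels are
drawn identically in both states, so every downstream stage has exact
ground truth: which channels carry state information and by how much.

This emulates a resting cohort of 8 subjects, 16 channels at 500 Hz,
2 minutes per state. It does not model volume conduction, eye-blink/EMG
artifacts, or non-stationarity within a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import BANDS, FeatureMatrix
from .io import EEGRecording, FATIGUE, PRE_FATIGUE

__all__ = ["SyntheticCohortConfig", "generate_cohort", "make_toy_feature_table"]

#: baseline variance (uV^2) of each band-limited component
_BASE_BAND_VAR = {"delta": 1.0, "theta": 0.8, "alpha": 1.0, "beta": 0.5}
_PINK_VAR = 0.3
_FIR_ORDER = 501  # taps; Hamming-windowed band-pass


@dataclass
class SyntheticCohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated experiment: 8 subjects, 16 channels,
    500 Hz, 120 s per state, 6 informative channels.
    """

    n_subjects: int = 8
    n_channels: int = 16
    fs: float = 500.0
    duration_per_state: float = 120.0
    informative_channels: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    band_effects: dict[str, float] = field(
        default_factory=lambda: {"alpha": 1.8, "theta": 1.5, "beta": 0.6}
    )
    #: AR(1) coefficient of the broadband noise: (pre-fatigue, fatigue)
    entropy_effect: tuple[float, float] = (0.3, 0.4)
    #: sd of the per-subject multiplicative jitter on effect sizes
    subject_variability: float = 0.1
    #: within-recording non-stationarity: sd of the log band-power envelope
    #: and of the AR-coefficient drift, redrawn every ``drift_block_s`` on
    #: every channel in both states (fatigue is a fluctuating state, and
    #: resting band power drifts too; without this, state effects are
    #: perfectly homogeneous across epochs and single features classify at
    #: ceiling, unlike any real cohort)
    band_drift_sd: float = 0.2
    ar_drift_sd: float = 0.12
    drift_block_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.informative_channels) <= set(range(self.n_channels)):
            raise ValueError("informative_channels out of range")
        if any(v <= 0 for v in self.band_effects.values()):
            raise ValueError("band_effects multipliers must be > 0")
        unknown = set(self.band_effects) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown band(s) in band_effects: {sorted(unknown)}")
        for phi in self.entropy_effect:
            if not 0 <= phi < 1:
                raise ValueError("AR(1) coefficients must be in [0, 1)")


def _bandpass_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], taps: np.ndarray
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (FIR filtered white noise)."""
    pad = len(taps)
    w = rng.standard_normal(n + 2 * pad)
    x = sps.lfilter(taps, 1.0, w)[pad + pad // 2 : pad + pad // 2 + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(
    rng: np.random.Generator, n: int, phi_blocks: np.ndarray, block_len: int
) -> np.ndarray:
    """Pink (1/f-amplitude) noise, AR(1)-smoothed with a per-block
    coefficient and renormalized to unit variance per block (the smoothing
    changes regularity, not power)."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC pole
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    out = np.empty(n)
    zi = np.zeros(1)
    for b, phi in enumerate(phi_blocks):
        seg = x[b * block_len : min((b + 1) * block_len, n)]
        if seg.size == 0:
            break
        y, zi = sps.lfilter([1.0], [1.0, -phi], seg, zi=zi)
        sd = y.std()
        out[b * block_len : b * block_len + len(y)] = y / sd if sd > 0 else y
    return out


def _fir_taps(fs: float) -> dict[str, np.ndarray]:
    taps = {}
    for name, (lo, hi) in BANDS.items():
        taps[name] = sps.firwin(
            _FIR_ORDER, [lo, hi], pass_zero=False, window="hamming", fs=fs
        )
    return taps


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[list[EEGRecording], dict]:
    """Generate two recordings (pre-fatigue, fatigue) per subject.

    Returns the recordings and a ground-truth dict with the informative
    channel labels/indices and the per-subject realized effect sizes.
    Bit-identical for identical configs (including seed).
    """
    cfg = config or SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_per_state * cfg.fs))
    taps = _fir_taps(cfg.fs)
    labels = [f"ch{i:02d}" for i in range(cfg.n_channels)]
    informative = set(cfg.informative_channels)
    phi_pre, phi_fat = cfg.entropy_effect

    recordings: list[EEGRecording] = []
    realized: dict[str, dict[str, list[float]]] = {}
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1}"
        # per-subject multiplicative jitter of the band effects
        jitter = {
            b: max(mult * (1 + cfg.subject_variability * rng.standard_normal()), 0.05)
            for b, mult in cfg.band_effects.items()
        }
        realized[sid] = {b: jitter[b] for b in jitter}
        block_len = max(1, int(round(cfg.drift_block_s * cfg.fs)))
        n_blocks = -(-n // block_len)
        for state in (PRE_FATIGUE, FATIGUE):
            sigs = np.empty((cfg.n_channels, n))
            for c in range(cfg.n_channels):
                x = np.zeros(n)
                affected = state == FATIGUE and c in informative
                for b in BANDS:
                    var = _BASE_BAND_VAR[b]
                    if affected and b in jitter:
                        var *= jitter[b]
                    # slow log-normal power drift, mean-equal across states
                    env = np.repeat(
                        np.exp(0.5 * cfg.band_drift_sd * rng.standard_normal(n_blocks)),
                        block_len,
                    )[:n]
                    x += np.sqrt(var) * env * _bandpass_noise(rng, n, cfg.fs, BANDS[b], taps[b])
                phi = phi_fat if affected else phi_pre
                phi_blocks = np.clip(
                    phi + cfg.ar_drift_sd * rng.standard_normal(n_blocks), 0.0, 0.95
                )
                x += np.sqrt(_PINK_VAR) * _pink_noise(rng, n, phi_blocks, block_len)
                sigs[c] = x
            recordings.append(
                EEGRecording(
                    signal=sigs,
                    fs=cfg.fs,
                    channel_labels=labels,
                    subject_id=sid,
                    state=state,
                )
            )
    ground_truth = {
        "informative_channels": sorted(informative),
        "informative_labels": [labels[i] for i in sorted(informative)],
        "band_effects": dict(cfg.band_effects),
        "realized_band_effects": realized,
        "entropy_effect": list(cfg.entropy_effect),
        "seed": cfg.seed,
    }
    return recordings, ground_truth


def make_toy_feature_table(
    n_samples: int = 200,
    n_features: int = 20,
    n_informative: int = 5,
    class_sep: float = 3.0,
    seed: int = 0,
    n_channels: int | None = None,
) -> FeatureMatrix:
    """Two-class Gaussian feature table for unit tests of the weighting and
    classification stages.

    Informative columns have class means separated by ``class_sep`` standard
    deviations; the rest are pure noise. Columns are assigned round-robin to
    ``n_channels`` pseudo-channels (default: one channel per column) so the
    table carries a valid (channel, feature) index.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = np.random.default_rng(seed)
    y = np.arange(n_samples) % 2
    rng.shuffle(y)
    X = rng.standard_normal((n_samples, n_features))
    X[:, :n_informative] += class_sep * y[:, None]
    if n_channels is None:
        columns = [(f"col{j:02d}", "f0") for j in range(n_features)]
    else:
        if n_features % n_channels:
            raise ValueError("n_features must be a multiple of n_channels")
        per = n_features // n_channels
        columns = [
            (f"col{c:02d}", f"f{k}") for c in range(n_channels) for k in range(per)
        ]
    return FeatureMatrix(
        values=X,
        column_index=columns,
        labels=y,
        subject_ids=np.full(n_samples, "toy"),
    )
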