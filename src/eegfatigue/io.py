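"""Reading, writing and epoching of multichannel EEG recordings.

Two on-disk formats are supported: EDF (European Data Format, the field's
interchange format for continuous recordings) and a plain CSV layout used
for dependency-free fixtures:

    fs=500
    Cz,FCz,F3
    <channel Cz samples, comma separated>
    <channel FCz samples>
    <channel F3 samples>

Values are microvolts throughout. Loading never filters or rereferences;
epoching is a plain sliding window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "EpochSet",
    "load_recording",
    "save_recording_csv",
    "write_edf",
    "segment",
    "segment_all",
]

PRE_FATIGUE, FATIGUE = 0, 1


class FormatError(ValueError):
    """Raised when a file parses but violates the recording contract."""


@dataclass
class EEGRecording:
    """One subject/state continuous multichannel signal.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Raw amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``signal``.
    subject_id : str
    state : int
        0 = pre-fatigue, 1 = fatigue.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "unknown"
    state: int = PRE_FATIGUE

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise FormatError("signal must be a 2-D (n_channels, n_samples) array")
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite values")
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        labels = list(self.channel_labels)
        if len(labels) != self.signal.shape[0]:
            raise FormatError("channel_labels length must equal n_channels")
        if len(set(labels)) != len(labels):
            raise FormatError("channel_labels must be unique")
        self.channel_labels = labels
        if self.state not in (PRE_FATIGUE, FATIGUE):
            raise FormatError(f"state must be 0 or 1, got {self.state}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length labeled windows cut from one or more recordings."""

    epochs: np.ndarray  # (n_epochs, n_channels, epoch_samples)
    labels: np.ndarray  # (n_epochs,) in {0, 1}
    subject_ids: np.ndarray  # (n_epochs,) of str
    fs: float
    epoch_len: float
    overlap: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, epoch_samples)")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        if len(self.labels) != len(self.epochs) or len(self.subject_ids) != len(self.epochs):
            raise ValueError("labels/subject_ids must align with epochs")
        expected = int(round(self.epoch_len * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch_samples {self.epochs.shape[2]} != round(epoch_len*fs) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def save(self, directory: str | Path) -> None:
        """Persist as ``epochs.csv`` (rows = epochs, channel-major flattening)
        plus a ``meta.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = self.epochs.reshape(self.n_epochs, -1)
        np.savetxt(directory / "epochs.csv", flat, delimiter=",")
        meta = {
            "shape": list(self.epochs.shape),
            "labels": self.labels.tolist(),
            "subject_ids": [str(s) for s in self.subject_ids],
            "fs": self.fs,
            "epoch_len": self.epoch_len,
            "overlap": self.overlap,
            "channel_labels": self.channel_labels,
        }
        (directory / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        flat = np.loadtxt(directory / "epochs.csv", delimiter=",", ndmin=2)
        epochs = flat.reshape(meta["shape"])
        return cls(
            epochs=epochs,
            labels=np.array(meta["labels"]),
            subject_ids=np.array(meta["subject_ids"]),
            fs=meta["fs"],
            epoch_len=meta["epoch_len"],
            overlap=meta["overlap"],
            channel_labels=meta["channel_labels"],
        )


# ---------------------------------------------------------------------------
# CSV format
# ---------------------------------------------------------------------------

def save_recording_csv(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording in the package's CSV layout (see module docstring)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"fs={recording.fs:g}\n")
        fh.write(",".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.signal, delimiter=",", fmt="%.10g")


def _load_csv(path: Path) -> tuple[np.ndarray, float, list[str]]:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.lower().startswith("fs="):
            raise FormatError(f"{path}: first line must be 'fs=<Hz>', got {header!r}")
        try:
            fs = float(header.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse sampling rate from {header!r}") from exc
        labels = [s.strip() for s in fh.readline().strip().split(",")]
        try:
            signal = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric sample value") from exc
    return signal, fs, labels


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_signal_rates(path: Path) -> tuple[int, list[int], float]:
    """Parse n_signals, per-signal samples-per-record and record duration
    straight from the EDF header (cheap contract check before a full read)."""
    with path.open("rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        record_dur = float(header[244:252].decode("ascii", "replace").strip() or 1)
        ns = int(header[252:256].decode("ascii", "replace").strip())
        sig = fh.read(ns * 256)
    # per-signal fields are stored field-major: all labels, all transducers, ...
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    nsamp = [int(sig[off + i * 8 : off + (i + 1) * 8].decode("ascii").strip()) for i in range(ns)]
    return ns, nsamp, record_dur


def _load_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    ns, nsamp, record_dur = _edf_signal_rates(path)
    if len(set(nsamp)) > 1:
        raise FormatError(
            f"{path}: channels have mismatched sampling rates "
            f"(samples per record: {sorted(set(nsamp))})"
        )
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne returns SI volts for EEG channels; recordings here are microvolts
    signal = raw.get_data() * 1e6
    return signal, float(raw.info["sfreq"]), list(raw.ch_names)


def write_edf(recording: EEGRecording, path: str | Path, record_duration: float = 1.0) -> None:
    """Minimal EDF writer (16-bit, one physical unit 'uV' for all channels).

    Covers what this package needs to export recordings and build EDF
    fixtures; it does not implement EDF+ annotations.
    """
    path = Path(path)
    sig = recording.signal
    n_ch = recording.n_channels
    spr = int(round(recording.fs * record_duration))
    n_records = sig.shape[1] // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record")
    used = sig[:, : n_records * spr]

    phys_min = used.min(axis=1)
    phys_max = used.max(axis=1)
    # widen degenerate ranges so the digital mapping is invertible
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def f(value: object, width: int) -> bytes:
        s = f"{value}"[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f(recording.subject_id, 80),
            f(f"state={recording.state}", 80),
            f("01.01.20", 8),
            f("00.00.00", 8),
            f(256 * (1 + n_ch), 8),
            f("", 44),
            f(n_records, 8),
            f(f"{record_duration:g}", 8),
            f(n_ch, 4),
        ]
    )
    fields = [
        [f(lbl, 16) for lbl in recording.channel_labels],
        [f("", 80)] * n_ch,
        [f("uV", 8)] * n_ch,
        [f(f"{v:.6g}"[:8], 8) for v in phys_min],
        [f(f"{v:.6g}"[:8], 8) for v in phys_max],
        [f(dig_min, 8)] * n_ch,
        [f(dig_max, 8)] * n_ch,
        [f("", 80)] * n_ch,
        [f(spr, 8)] * n_ch,
        [f("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(col) for col in fields)

    # re-read the 8-char physical min/max strings so the scaling we encode
    # matches exactly what a reader will parse back
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (pmax - pmin) / (dig_max - dig_min)
    digital = np.round((used - pmin[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with path.open("wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(n_ch):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Public loading
# ---------------------------------------------------------------------------

def load_recording(
    path: str | Path,
    format: str | None = None,
    subject_id: str = "unknown",
    state: int = PRE_FATIGUE,
) -> EEGRecording:
    """Load a recording from EDF or CSV; values are returned unchanged.

    Parameters
    ----------
    path : path to the file.
    format : "edf" or "csv"; inferred from the suffix when None.
    subject_id, state : metadata attached to the recording.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        signal, fs, labels = _load_csv(path)
    elif format == "edf":
        signal, fs, labels = _load_edf(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'csv')")
    return EEGRecording(signal=signal, fs=fs, channel_labels=labels,
                        subject_id=subject_id, state=state)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(recording: EEGRecording, epoch_len: float = 1.0, overlap: float = 0.0) -> EpochSet:
    """Cut a recording into sliding windows of ``epoch_len`` seconds.

    Step = epoch_len - overlap; a trailing partial window is dropped. Every
    epoch inherits the recording's state label and subject id.
    """
    if not 0 <= overlap < epoch_len:
        raise ValueError(f"need 0 <= overlap < epoch_len, got {overlap}, {epoch_len}")
    n = int(round(epoch_len * recording.fs))
    step = int(round((epoch_len - overlap) * recording.fs))
    if step < 1:
        raise ValueError("epoch step is below one sample")
    if recording.n_samples < n:
        raise ValueError(
            f"recording of {recording.duration:g} s is shorter than one "
            f"{epoch_len:g} s epoch"
        )
    starts = np.arange(0, recording.n_samples - n + 1, step)
    epochs = np.stack([recording.signal[:, s : s + n] for s in starts])
    return EpochSet(
        epochs=epochs,
        labels=np.full(len(starts), recording.state),
        subject_ids=np.full(len(starts), recording.subject_id),
        fs=recording.fs,
        epoch_len=epoch_len,
        overlap=overlap,
        channel_labels=list(recording.channel_labels),
    )


def segment_all(
    recordings: list[EEGRecording], epoch_len: float = 1.0, overlap: float = 0.0
) -> EpochSet:
    """Segment each recording independently and concatenate the epochs.

    No epoch ever spans the boundary between two recordings.
    """
    if not recordings:
        raise ValueError("no recordings given")
    parts = [segment(r, epoch_len, overlap) for r in recordings]
    first = parts[0]
    for p in parts[1:]:
        if p.channel_labels != first.channel_labels or p.fs != first.fs:
            raise ValueError("recordings disagree on channels or sampling rate")
    return EpochSet(
        epochs=np.concatenate([p.epochs for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        fs=first.fs,
        epoch_len=epoch_len,
        overlap=overlap,
        channel_labels=first.channel_labels,
    )
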