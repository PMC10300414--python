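"""Reading, writing and preprocessing of sleep-EEG recordings and hypnograms.

The conventions follow routine clinical polysomnography: six EEG channels
(F3, F4, C3, C4, O1, O2) sampled at 200 Hz, scored in 30-s epochs with one
of five stage labels (W, N1, N2, N3, R).  Recordings travel as EDF files;
hypnograms and subject metadata as small CSV tables.

EDF files are written by a minimal built-in 16-bit EDF writer and read back
through :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "STAGES",
    "CANONICAL_CHANNELS",
    "EPOCH_SECONDS",
    "DEFAULT_FS",
    "Recording",
    "Hypnogram",
    "SubjectMeta",
    "ChannelNotFoundError",
    "FormatError",
    "HypnogramParseError",
    "read_recording",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_metadata",
    "write_metadata",
    "bandpass",
    "segment_epochs",
    "segment_unlabeled",
]

#: Stage labels in canonical order (wake, light→deep non-REM, REM).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: EEG channel montage used throughout, frontal/central/occipital pairs.
CANONICAL_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "O1", "O2")

#: Scoring epoch length in seconds.
EPOCH_SECONDS: float = 30.0

#: Expected sampling rate in Hz.
DEFAULT_FS: float = 200.0

AGE_GROUPS: tuple[str, ...] = ("younger", "older")
OSA_CLASSES: tuple[str, ...] = ("healthy", "mtom", "severe")


class ChannelNotFoundError(KeyError):
    """A requested channel is absent from the recording."""


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


class HypnogramParseError(FormatError):
    """A hypnogram file contains an unknown stage token or is empty."""


@dataclass
class Recording:
    """Multichannel EEG time series.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One unique name per row of ``signals``.
    subject_id
        Identifier carried through the pipeline.
    """

    signals: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (n_channels, n_samples) array")
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signals.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.signals.shape[0] < 1:
            raise ValueError("need at least one channel")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def pick(self, channels: Sequence[str]) -> "Recording":
        """Return a copy restricted to ``channels`` in the requested order."""
        idx = []
        for ch in channels:
            if ch not in self.channel_names:
                raise ChannelNotFoundError(
                    f"channel {ch!r} not present (have {list(self.channel_names)})"
                )
            idx.append(self.channel_names.index(ch))
        return Recording(
            self.signals[idx].copy(), self.fs, tuple(channels), self.subject_id
        )


@dataclass
class Hypnogram:
    """Ordered stage labels, one per 30-s epoch."""

    stages: tuple[str, ...]
    epoch_seconds: float = EPOCH_SECONDS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage labels {sorted(set(bad))}; valid: {STAGES}")

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)


@dataclass
class SubjectMeta:
    """Per-subject demographic / diagnostic metadata."""

    subject_id: str
    age_group: str
    osa_class: str
    spo2: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")
        if self.osa_class not in OSA_CLASSES:
            raise ValueError(f"osa_class must be one of {OSA_CLASSES}, got {self.osa_class!r}")
        if self.spo2 is not None and not (0.0 < self.spo2 <= 100.0):
            raise ValueError(f"spo2 must lie in (0, 100], got {self.spo2}")


# ---------------------------------------------------------------------------
# EDF writing (minimal 16-bit writer) and reading (via mne)
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if isinstance(value, float):
        s = f"{value:.6g}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file (physical dimension µV).

    Uses 1-s data records; trailing samples short of a full second are
    dropped with a warning.  Per-channel physical ranges are symmetric
    around zero and sized to the data, so quantization error is at most
    ``max|x| / 32767`` per channel.
    """
    path = Path(path)
    spr = int(round(rec.fs))  # samples per 1-s record
    if abs(spr - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    if n_records * spr != rec.n_samples:
        warnings.warn(
            f"dropping {rec.n_samples - n_records * spr} trailing samples "
            "that do not fill a 1-s EDF record"
        )
    data = rec.signals[:, : n_records * spr]
    nch = rec.n_channels

    # quantize with the exact (ASCII-rounded) ranges written to the header,
    # using the same affine map EDF readers invert
    dig_min, dig_max = -32768, 32767
    phys_max = np.array([
        float(_ascii_field(float(v), 8).decode())
        for v in np.maximum(np.abs(data).max(axis=1) * 1.0001, 1.0)
    ])
    scale = 2.0 * phys_max / (dig_max - dig_min)
    digital = np.clip(
        np.round((data + phys_max[:, None]) / scale[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    header = b""
    header += _ascii_field("0", 8)  # version
    header += _ascii_field(rec.subject_id or "X", 80)  # patient id
    header += _ascii_field("synthetic sleep EEG", 80)  # recording id
    header += _ascii_field("01.01.00", 8)  # start date
    header += _ascii_field("00.00.00", 8)  # start time
    header += _ascii_field(256 * (1 + nch), 8)  # header bytes
    header += _ascii_field("", 44)  # reserved
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)  # record duration (s)
    header += _ascii_field(nch, 4)

    def sig_fields(fmt, width):
        return b"".join(_ascii_field(fmt(i), width) for i in range(nch))

    header += sig_fields(lambda i: f"EEG {rec.channel_names[i]}", 16)
    header += sig_fields(lambda i: "", 80)  # transducer
    header += sig_fields(lambda i: "uV", 8)  # physical dimension
    header += sig_fields(lambda i: -phys_max[i], 8)
    header += sig_fields(lambda i: phys_max[i], 8)
    header += sig_fields(lambda i: dig_min, 8)
    header += sig_fields(lambda i: dig_max, 8)
    header += sig_fields(lambda i: "BP 0.5-50Hz", 80)  # prefilter
    header += sig_fields(lambda i: spr, 8)
    header += sig_fields(lambda i: "", 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major, channel blocks inside each record
        blocks = digital.reshape(nch, n_records, spr)
        for r in range(n_records):
            for c in range(nch):
                fh.write(blocks[c, r].tobytes())
    return path


def read_recording(
    path: str | Path,
    channels: Sequence[str] = CANONICAL_CHANNELS,
    expected_fs: float | None = DEFAULT_FS,
    on_fs_mismatch: str = "error",
) -> Recording:
    """Read an EDF recording restricted to ``channels`` in the given order.

    Parameters
    ----------
    channels
        Channel names to keep, in the order they should appear.
    expected_fs
        Sampling rate the downstream feature arithmetic assumes
        (200 Hz by default).  ``None`` disables the check.
    on_fs_mismatch
        ``"error"`` (default) rejects files whose rate differs from
        ``expected_fs``; ``"resample"`` applies polyphase resampling.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc

    # mne prefixes EEG channel labels; accept either bare or prefixed names
    name_map = {}
    for ch in raw.ch_names:
        name_map[ch] = ch
        if ch.startswith("EEG "):
            name_map.setdefault(ch[4:].strip(), ch)
    picks = []
    for ch in channels:
        if ch not in name_map:
            raise ChannelNotFoundError(
                f"channel {ch!r} not found in {path.name} (file has {raw.ch_names})"
            )
        picks.append(name_map[ch])
    data = raw.get_data(picks=picks, units="uV")
    fs = float(raw.info["sfreq"])

    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        if on_fs_mismatch == "resample":
            warnings.warn(
                f"{path.name}: resampling from {fs} Hz to {expected_fs} Hz"
            )
            from fractions import Fraction

            frac = Fraction(expected_fs / fs).limit_denominator(1000)
            data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
            fs = expected_fs
        else:
            raise FormatError(
                f"{path.name}: sampling rate {fs} Hz differs from the expected "
                f"{expected_fs} Hz (pass on_fs_mismatch='resample' to resample)"
            )
    return Recording(data, fs, tuple(channels), subject_id=path.stem)


# ---------------------------------------------------------------------------
# Hypnogram and metadata CSV
# ---------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    """Write ``epoch,stage`` CSV with 0-based epoch numbers."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "stage"])
        for i, s in enumerate(hyp.stages):
            w.writerow([i, s])
    return path


def read_hypnogram(path: str | Path, subject_id: str | None = None) -> Hypnogram:
    """Read an ``epoch,stage`` CSV into a :class:`Hypnogram`."""
    path = Path(path)
    stages: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise HypnogramParseError(f"{path}: empty hypnogram file")
        if [h.strip().lower() for h in header[:2]] != ["epoch", "stage"]:
            raise HypnogramParseError(
                f"{path}: expected header 'epoch,stage', got {header}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            token = row[1].strip()
            if token not in STAGES:
                raise HypnogramParseError(
                    f"{path}: unknown stage token {token!r} at row {row_no}"
                )
            stages.append(token)
    if not stages:
        raise HypnogramParseError(f"{path}: no stage rows")
    return Hypnogram(tuple(stages), subject_id=subject_id or path.stem)


def write_metadata(metas: Iterable[SubjectMeta], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "age_group", "osa_class", "spo2"])
        for m in metas:
            w.writerow([m.subject_id, m.age_group, m.osa_class,
                        "" if m.spo2 is None else f"{m.spo2:.4f}"])
    return path


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    metas = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            spo2 = row.get("spo2", "")
            metas.append(SubjectMeta(
                subject_id=row["subject_id"],
                age_group=row["age_group"],
                osa_class=row["osa_class"],
                spo2=float(spo2) if spo2 not in ("", None) else None,
            ))
    return metas


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bandpass(
    rec: Recording, low: float = 0.5, high: float = 50.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth bandpass (default 0.5–50 Hz, order 4).

    Applied forward-backward (``sosfiltfilt``) so transient waveforms such
    as K-complexes are not phase-distorted.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist rate {nyq} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signals, axis=1)
    return Recording(filtered, rec.fs, rec.channel_names, rec.subject_id)


def segment_unlabeled(rec: Recording, epoch_seconds: float = EPOCH_SECONDS) -> list[np.ndarray]:
    """Cut a recording into full epochs, dropping the trailing partial epoch."""
    spe = int(round(rec.fs * epoch_seconds))
    if abs(spe - rec.fs * epoch_seconds) > 1e-9:
        raise ValueError("fs * epoch_seconds must be an integer sample count")
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than one "
            f"{epoch_seconds:.0f}-s epoch"
        )
    return [rec.signals[:, i * spe : (i + 1) * spe] for i in range(n_epochs)]


def segment_epochs(
    rec: Recording, hyp: Hypnogram, mismatch: str = "warn"
) -> list[tuple[np.ndarray, str]]:
    """Pair 30-s signal blocks with hypnogram labels, in temporal order.

    Returns ``min(full epochs in recording, len(hyp))`` pairs.  A length
    mismatch truncates to the shorter side; ``mismatch="error"`` raises
    instead of warning.
    """
    blocks = segment_unlabeled(rec, hyp.epoch_seconds)
    n = min(len(blocks), len(hyp))
    if len(blocks) != len(hyp):
        msg = (
            f"recording holds {len(blocks)} full epochs but hypnogram has "
            f"{len(hyp)} labels; truncating to {n}"
        )
        if mismatch == "error":
            raise ValueError(msg)
        warnings.warn(msg)
    return [(blocks[i], hyp.stages[i]) for i in range(n)]
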