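"""Per-epoch spectral features for sleep staging.

Each 30-s epoch of each channel is turned into a short-time Fourier
spectrogram (1-s Hann windows, 50% overlap → 59 windows at 200 Hz), every
window's power spectrum is normalized by its own in-band sum (relative
PSD, so features are amplitude-invariant), and eight band features are
extracted per channel:

====  ===========  =============================================
#     name         definition over the 59 windows
====  ===========  =============================================
1     low_delta    mean relative power in (0.5, 2] Hz
2     K_comp_1     max  relative power in (1, 4] Hz (delta)
3     K_comp_2     mean of the remaining 58 delta values
4     theta        mean relative power in (4, 8] Hz
5     alpha        mean relative power in (8, 12] Hz
6     spindle_1    max  relative power in (12, 15] Hz (sigma)
7     spindle_2    mean of the remaining 58 sigma values
8     beta         mean relative power in (15, 30] Hz
====  ===========  =============================================

The max/mean-of-rest pairs act as detectors for K-complexes (brief
high-amplitude delta transients) and sleep spindles (brief sigma bursts):
a single 0.5–1.5 s event dominates one STFT window and lifts the maximum
well above the mean of the other windows.  With six channels this yields
the 48-dimensional per-epoch feature vector.

Band membership uses half-open, upper-inclusive intervals (low, high]; at
the 1-Hz bin resolution of a 1-s window this puts bins {1, 2} in
low_delta, {2, 3, 4} in delta, and so on.  low_delta and delta overlap at
2 Hz by construction of the band table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .io import CANONICAL_CHANNELS, EPOCH_SECONDS

__all__ = [
    "BandScheme",
    "Spectrogram",
    "EpochFeatures",
    "DEFAULT_SCHEME",
    "FEATURE_NAMES_PER_CHANNEL",
    "epoch_feature_names",
    "compute_spectrogram",
    "normalize_psd",
    "band_fraction",
    "extract_channel_features",
    "extract_epoch_features",
    "featurize_subject",
    "featurize_epochs",
    "feature_columns",
]

#: Per-channel feature names in output order.
FEATURE_NAMES_PER_CHANNEL: tuple[str, ...] = (
    "low_delta", "K_comp_1", "K_comp_2", "theta",
    "alpha", "spindle_1", "spindle_2", "beta",
)

WINDOW_SECONDS = 1.0
OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class BandScheme:
    """Frequency band table and the normalization range.

    ``bands`` maps band name → (low, high) in Hz with half-open
    upper-inclusive membership; ``analysis_range`` is the (low, high]
    range whose bins form the relative-PSD denominator.
    """

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "low_delta": (0.5, 2.0),
        "delta": (1.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "sigma": (12.0, 15.0),
        "beta": (15.0, 30.0),
    })
    analysis_range: tuple[float, float] = (0.5, 50.0)

    def __post_init__(self) -> None:
        lo_a, hi_a = self.analysis_range
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low {lo} must be < high {hi}")
            if lo < lo_a - 1e-12 or hi > hi_a + 1e-12:
                raise ValueError(
                    f"band {name!r} ({lo}, {hi}] outside analysis range "
                    f"({lo_a}, {hi_a}]"
                )

    def band_mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        return (freqs > lo) & (freqs <= hi + 1e-12)

    def analysis_mask(self, freqs: np.ndarray) -> np.ndarray:
        lo, hi = self.analysis_range
        return (freqs > lo) & (freqs <= hi + 1e-12)


DEFAULT_SCHEME = BandScheme()


@dataclass
class Spectrogram:
    """STFT power per window: ``power[w, k]`` at window w, frequency bin k."""

    power: np.ndarray          # (n_windows, n_bins), nonnegative
    freqs: np.ndarray          # bin frequencies in Hz
    window_seconds: float = WINDOW_SECONDS
    overlap_fraction: float = OVERLAP_FRACTION
    relative: bool = False
    degenerate_windows: np.ndarray | None = None  # bool mask, set by normalize_psd

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]


@dataclass
class EpochFeatures:
    """48-vector of per-epoch features, channel-major (F3 block first)."""

    values: np.ndarray
    names: tuple[str, ...]


def epoch_feature_names(
    channels: Sequence[str] = CANONICAL_CHANNELS,
) -> tuple[str, ...]:
    """``channel.feature`` names in channel-major order (48 for 6 channels)."""
    return tuple(
        f"{ch}.{feat}" for ch in channels for feat in FEATURE_NAMES_PER_CHANNEL
    )


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Slice the last axis into overlapping frames -> (..., n_frames, win)."""
    n = x.shape[-1]
    n_frames = (n - win) // hop + 1
    idx = hop * np.arange(n_frames)[:, None] + np.arange(win)[None, :]
    return x[..., idx]


def compute_spectrogram(epoch_signal: np.ndarray, fs: float) -> Spectrogram:
    """STFT power spectrogram of one epoch of one channel.

    1-s Hann-tapered windows with 50% overlap and no zero-padding, power
    equal to the squared magnitude of the windowed DFT.  A 30-s epoch
    yields 2·30 − 1 = 59 windows with bins at 0, 1, …, fs/2 Hz.
    """
    x = np.asarray(epoch_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch_signal must be 1-D; use extract_epoch_features "
                         "for multichannel blocks")
    win = int(round(fs * WINDOW_SECONDS))
    if abs(win - fs * WINDOW_SECONDS) > 1e-9:
        raise ValueError("fs times the 1-s window must be an integer")
    hop = win // 2
    if x.shape[-1] < win:
        raise ValueError(
            f"epoch of {x.shape[-1]} samples shorter than one {win}-sample window"
        )
    expected = int(round(fs * EPOCH_SECONDS))
    if x.shape[-1] != expected:
        raise ValueError(
            f"expected an epoch of {expected} samples (fs·30 s), got {x.shape[-1]}"
        )
    taper = hann(win, sym=False)
    frames = _frame(x, win, hop) * taper
    power = np.abs(np.fft.rfft(frames, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    return Spectrogram(power=power, freqs=freqs)


def normalize_psd(spec: Spectrogram, scheme: BandScheme = DEFAULT_SCHEME) -> Spectrogram:
    """Normalize each window's PSD by its sum over the analysis range.

    After normalization every window's bins inside the analysis range sum
    to 1 and bins outside it are zero.  Windows with zero in-range power
    are left all-zero and flagged in ``degenerate_windows``.
    """
    mask = scheme.analysis_mask(spec.freqs)
    inband = spec.power[:, mask]
    totals = inband.sum(axis=1)
    degenerate = totals <= 0.0
    rel = np.zeros_like(spec.power)
    safe = ~degenerate
    rel[np.ix_(safe, mask)] = inband[safe] / totals[safe, None]
    return Spectrogram(
        power=rel,
        freqs=spec.freqs,
        window_seconds=spec.window_seconds,
        overlap_fraction=spec.overlap_fraction,
        relative=True,
        degenerate_windows=degenerate,
    )


def band_fraction(
    relative_window: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float],
    scheme: BandScheme = DEFAULT_SCHEME,
) -> float:
    """Sum of relative power over bins f with low < f ≤ high."""
    lo, hi = band
    lo_a, hi_a = scheme.analysis_range
    if lo < lo_a - 1e-12 or hi > hi_a + 1e-12 or not lo < hi:
        raise ValueError(
            f"band ({lo}, {hi}] invalid or outside analysis range ({lo_a}, {hi_a}]"
        )
    sel = (freqs > lo) & (freqs <= hi + 1e-12)
    return float(np.sum(relative_window[..., sel], axis=-1))


def _features_from_fractions(frac: np.ndarray) -> np.ndarray:
    """Map window band fractions (..., n_windows, 6 bands) to 8 features.

    Band columns follow DEFAULT_SCHEME order:
    low_delta, delta, theta, alpha, sigma, beta.  The "remaining" means
    exclude the single argmax window (first occurrence on ties).
    """
    n_win = frac.shape[-2]
    if n_win < 2:
        raise ValueError("need at least 2 windows for max/mean-of-rest features")
    low_delta = frac[..., 0].mean(axis=-1)
    theta = frac[..., 2].mean(axis=-1)
    alpha = frac[..., 3].mean(axis=-1)
    beta = frac[..., 5].mean(axis=-1)

    def max_and_rest(col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mx = col.max(axis=-1)
        rest = (col.sum(axis=-1) - mx) / (n_win - 1)
        return mx, rest

    k1, k2 = max_and_rest(frac[..., 1])
    s1, s2 = max_and_rest(frac[..., 4])
    return np.stack([low_delta, k1, k2, theta, alpha, s1, s2, beta], axis=-1)


def _epoch_band_fractions(
    block: np.ndarray, fs: float, scheme: BandScheme
) -> np.ndarray:
    """Vectorized relative band fractions, shape (n_channels, n_windows, 6)."""
    win = int(round(fs * WINDOW_SECONDS))
    hop = win // 2
    taper = hann(win, sym=False)
    frames = _frame(np.asarray(block, dtype=float), win, hop) * taper
    power = np.abs(np.fft.rfft(frames, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)

    amask = scheme.analysis_mask(freqs)
    totals = power[..., amask].sum(axis=-1)
    if np.all(totals <= 0.0):
        raise ValueError("all-zero epoch: relative PSD undefined")
    if np.any(totals <= 0.0):
        warnings.warn("epoch contains zero-power windows; their relative "
                      "values are set to 0")
    safe_totals = np.where(totals > 0.0, totals, 1.0)
    indicator = np.stack(
        [scheme.band_mask(freqs, name).astype(float) for name in scheme.bands],
        axis=-1,
    )  # (n_bins, 6)
    frac = (power @ indicator) / safe_totals[..., None]
    frac[totals <= 0.0] = 0.0
    return frac


def extract_channel_features(
    epoch_channel_signal: np.ndarray,
    fs: float,
    scheme: BandScheme = DEFAULT_SCHEME,
) -> np.ndarray:
    """Eight spectral features for one channel of one epoch."""
    x = np.asarray(epoch_channel_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D signal")
    frac = _epoch_band_fractions(x[None, :], fs, scheme)[0]
    return _features_from_fractions(frac)


def extract_epoch_features(
    epoch_block: np.ndarray,
    fs: float,
    scheme: BandScheme = DEFAULT_SCHEME,
    channels: Sequence[str] = CANONICAL_CHANNELS,
) -> EpochFeatures:
    """48 features for one 6-channel epoch block, channel-major order."""
    block = np.asarray(epoch_block, dtype=float)
    if block.ndim != 2 or block.shape[0] != len(channels):
        raise ValueError(
            f"expected a ({len(channels)}, fs·30) block, got shape {block.shape}"
        )
    frac = _epoch_band_fractions(block, fs, scheme)
    feats = _features_from_fractions(frac)  # (n_channels, 8)
    return EpochFeatures(values=feats.ravel(), names=epoch_feature_names(channels))


def featurize_epochs(
    epochs: Sequence[tuple[np.ndarray, str]],
    fs: float,
    scheme: BandScheme = DEFAULT_SCHEME,
    subject_id: str = "",
    channels: Sequence[str] = CANONICAL_CHANNELS,
) -> pd.DataFrame:
    """Feature matrix for a list of (epoch block, stage label) pairs.

    Returns a DataFrame with columns ``subject_id, epoch, stage`` followed
    by the 48 named feature columns, one row per epoch.
    """
    if len(epochs) == 0:
        raise ValueError("no epochs to featurize")
    names = epoch_feature_names(channels)
    rows = np.empty((len(epochs), len(names)))
    labels = []
    for i, (block, label) in enumerate(epochs):
        rows[i] = extract_epoch_features(block, fs, scheme, channels).values
        labels.append(label)
    df = pd.DataFrame(rows, columns=list(names))
    df.insert(0, "stage", labels)
    df.insert(0, "epoch", np.arange(len(epochs)))
    df.insert(0, "subject_id", subject_id)
    return df


# Alias matching the pipeline vocabulary: one subject's epochs -> matrix.
featurize_subject = featurize_epochs


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature column names of a feature matrix (non-metadata columns)."""
    meta = {"subject_id", "epoch", "stage", "age_group", "osa_class", "spo2"}
    return [c for c in df.columns if c not in meta]
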