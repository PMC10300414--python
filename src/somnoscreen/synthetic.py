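"""Synthetic polysomnography cohorts for end-to-end testing.

Generates hypnograms (first-order Markov chains over the five stages),
stage-conditioned six-channel EEG, OSA-severity effects and SpO₂ values,
all reproducible from a single master seed.

Each epoch's background is band-limited Gaussian noise whose relative
band powers follow the stage template: alpha-dominant wake, theta-heavy
N1, mixed N2 with K-complex and spindle transients, low-delta-dominated
N3, and mixed REM.  Transient events follow the scoring conventions for
N2 — K-complexes (high-amplitude biphasic delta-band wavelets) and
sleep spindles (Hann-enveloped 13.5 Hz bursts), each lasting
0.5–1.5 s at a default rate of 0.5 events per epoch ("approximately
every two epochs").  OSA severity acts multiplicatively: K-complex
amplitude and rate fall with severity while background beta power (and
REM sigma power) rise, which reproduces the group-difference directions
the screening models rely on.  SpO₂ is drawn per subject from its
age × severity cell's normal distribution truncated to (0, 100].

The six channels share a common stage-driven component plus 20%
independent per-channel noise, so they are correlated but not redundant.
The templates are testbed defaults, not claims about real EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (AGE_GROUPS, CANONICAL_CHANNELS, DEFAULT_FS, EPOCH_SECONDS,
                 OSA_CLASSES, STAGES, Hypnogram, Recording, SubjectMeta)

__all__ = [
    "GEN_BANDS",
    "StageTemplate",
    "OsaEffect",
    "CohortSpec",
    "Cohort",
    "DEFAULT_TEMPLATES",
    "DEFAULT_OSA_EFFECTS",
    "DEFAULT_TRANSITIONS",
    "SPO2_PARAMS",
    "simulate_hypnogram",
    "simulate_epoch",
    "simulate_subject",
    "simulate_cohort",
    "make_kcomplex",
    "make_spindle",
]

#: Spectral components of the background noise (half-open (low, high] Hz).
GEN_BANDS: dict[str, tuple[float, float]] = {
    "low": (0.5, 4.0),     # delta range incl. the slow 0.5-2 Hz component
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 15.0),
    "beta": (15.0, 30.0),
}


@dataclass(frozen=True)
class StageTemplate:
    """Relative band-power targets and event statistics for one stage."""

    band_powers: dict[str, float]
    kcomplex_rate: float = 0.0     # expected events per 30-s epoch
    spindle_rate: float = 0.0
    event_duration: tuple[float, float] = (0.5, 1.5)  # seconds
    kcomplex_amp: float = 5.0      # amplitude multiple of background SD
    spindle_amp: float = 3.0

    def __post_init__(self) -> None:
        for name, p in self.band_powers.items():
            if name not in GEN_BANDS:
                raise ValueError(f"unknown band {name!r}")
            if p < 0:
                raise ValueError(f"band power {name} must be nonnegative")
        lo, hi = self.event_duration
        if not 0.0 < lo <= hi:
            raise ValueError("event_duration must satisfy 0 < low <= high")


#: Stage-dependent spectral content: alpha-dominant wake, theta N1,
#: K-complex+spindle N2, low-delta N3, mixed REM.
DEFAULT_TEMPLATES: dict[str, StageTemplate] = {
    "W": StageTemplate({"low": 0.15, "theta": 0.15, "alpha": 0.45,
                        "sigma": 0.05, "beta": 0.20}),
    "N1": StageTemplate({"low": 0.25, "theta": 0.45, "alpha": 0.10,
                         "sigma": 0.05, "beta": 0.15}),
    "N2": StageTemplate({"low": 0.35, "theta": 0.30, "alpha": 0.10,
                         "sigma": 0.10, "beta": 0.15},
                        kcomplex_rate=0.5, spindle_rate=0.5),
    "N3": StageTemplate({"low": 0.70, "theta": 0.15, "alpha": 0.05,
                         "sigma": 0.03, "beta": 0.07}),
    "R": StageTemplate({"low": 0.20, "theta": 0.35, "alpha": 0.15,
                        "sigma": 0.05, "beta": 0.25}),
}


@dataclass(frozen=True)
class OsaEffect:
    """Multiplicative severity effects applied to a subject's templates."""

    kcomplex_amp: float = 1.0   # < 1 with severity (K-complexes weaken)
    kcomplex_rate: float = 1.0  # < 1 with severity
    beta_power: float = 1.0     # > 1 with severity (beta background rises)
    rem_sigma_power: float = 1.0  # > 1 with severity (REM sigma rises)
    low_power: float = 1.0      # < 1 with severity (slow-wave background
    #                             falls, so the delta-band means drop too)

    def __post_init__(self) -> None:
        for v in (self.kcomplex_amp, self.kcomplex_rate,
                  self.beta_power, self.rem_sigma_power, self.low_power):
            if v <= 0:
                raise ValueError("effect multipliers must be positive")


DEFAULT_OSA_EFFECTS: dict[str, OsaEffect] = {
    "healthy": OsaEffect(),
    "mtom": OsaEffect(kcomplex_amp=0.80, kcomplex_rate=0.80,
                      beta_power=1.18, rem_sigma_power=1.10,
                      low_power=0.93),
    "severe": OsaEffect(kcomplex_amp=0.55, kcomplex_rate=0.60,
                        beta_power=1.40, rem_sigma_power=1.25,
                        low_power=0.85),
}

#: Row-stochastic stage transition matrix over (W, N1, N2, N3, R),
#: shaped to give realistic dwell times and all five stages within a
#: few hours of simulated sleep.
DEFAULT_TRANSITIONS = np.array([
    # W     N1     N2     N3     R
    [0.70, 0.25, 0.03, 0.01, 0.01],
    [0.10, 0.40, 0.45, 0.01, 0.04],
    [0.03, 0.05, 0.72, 0.12, 0.08],
    [0.01, 0.02, 0.25, 0.70, 0.02],
    [0.05, 0.10, 0.10, 0.01, 0.74],
])

#: SpO2 mean ± SD per (age_group, osa_class) cell, percent saturation.
SPO2_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("younger", "healthy"): (89.40, 8.07),
    ("older", "healthy"): (88.40, 6.41),
    ("younger", "mtom"): (82.92, 4.39),
    ("older", "mtom"): (83.70, 5.84),
    ("younger", "severe"): (73.40, 10.95),
    ("older", "severe"): (74.92, 7.90),
}


@dataclass
class CohortSpec:
    """Everything needed to generate a reproducible cohort."""

    subjects_per_cell: int | dict[tuple[str, str], int] = 5
    epochs_per_subject: int = 200
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_stage: str = "W"
    templates: dict[str, StageTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    effects: dict[str, OsaEffect] = field(
        default_factory=lambda: dict(DEFAULT_OSA_EFFECTS))
    spo2_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(SPO2_PARAMS))
    fs: float = DEFAULT_FS
    subject_jitter: float = 0.08   # lognormal sigma on per-subject band powers
    shared_fraction: float = 0.8   # variance share of the common component
    amplitude_uv: float = 20.0     # nominal background SD in microvolts
    seed: int = 0

    def n_in_cell(self, age_group: str, osa_class: str) -> int:
        if isinstance(self.subjects_per_cell, dict):
            return self.subjects_per_cell.get((age_group, osa_class), 0)
        return self.subjects_per_cell


@dataclass
class Cohort:
    recordings: dict[str, Recording]
    hypnograms: dict[str, Hypnogram]
    metadata: pd.DataFrame   # subject_id, age_group, osa_class, spo2

    @property
    def metas(self) -> list[SubjectMeta]:
        return [
            SubjectMeta(r.subject_id, r.age_group, r.osa_class,
                        None if pd.isna(r.spo2) else float(r.spo2))
            for r in self.metadata.itertuples()
        ]


def simulate_hypnogram(
    n_epochs: int,
    transition_matrix: np.ndarray = DEFAULT_TRANSITIONS,
    initial_stage: str = "W",
    seed: int | np.random.Generator = 0,
) -> Hypnogram:
    """First-order Markov stage sequence of length ``n_epochs``."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (5, 5):
        raise ValueError("transition matrix must be 5x5 over (W,N1,N2,N3,R)")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must be stochastic (sum to 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    state = STAGES.index(initial_stage)
    seq = []
    for _ in range(n_epochs):
        seq.append(STAGES[state])
        state = rng.choice(5, p=P[state])
    return Hypnogram(tuple(seq))


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band_powers: dict[str, float]
) -> np.ndarray:
    """Gaussian noise with prescribed relative band powers.

    Built in the frequency domain: a white complex-Gaussian spectrum is
    scaled per band so each band contributes its target share of the
    variance, then inverted.  This gives direct, exact control of the
    relative PSD — which is the downstream feature space.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    for name, p in band_powers.items():
        lo, hi = GEN_BANDS[name]
        mask = (freqs > lo) & (freqs <= hi)
        nb = int(mask.sum())
        if nb and p > 0:
            gain[mask] = np.sqrt(p / nb)
    spectrum = np.fft.rfft(rng.standard_normal(n)) * gain
    x = np.fft.irfft(spectrum, n=n)
    return x


def make_kcomplex(
    duration: float, fs: float, amplitude: float, freq: float = 2.5
) -> np.ndarray:
    """Hann-windowed biphasic delta-band wavelet (default 2.5 Hz).

    The center frequency sits inside the 1–4 Hz delta band so the
    transient registers on the max-delta detector; at the 1-Hz bin
    resolution of 1-s analysis windows, a slower (~1 Hz) wave would leave
    most of its energy below the band.
    """
    m = max(int(round(duration * fs)), 8)
    t = np.arange(m) / fs
    return amplitude * np.sin(2.0 * np.pi * freq * t) * np.hanning(m)


def make_spindle(
    duration: float, fs: float, amplitude: float, freq: float = 13.5
) -> np.ndarray:
    """Hann-enveloped sigma-band (default 13.5 Hz) burst."""
    m = max(int(round(duration * fs)), 8)
    t = np.arange(m) / fs
    return amplitude * np.sin(2.0 * np.pi * freq * t) * np.hanning(m)


def _place_event(signal: np.ndarray, event: np.ndarray,
                 rng: np.random.Generator) -> None:
    start = int(rng.integers(0, max(len(signal) - len(event), 1)))
    signal[start:start + len(event)] += event[: len(signal) - start]


def simulate_epoch(
    stage: str,
    template: StageTemplate | None = None,
    fs: float = DEFAULT_FS,
    rng: np.random.Generator | int = 0,
    effect: OsaEffect | None = None,
    n_channels: int = len(CANONICAL_CHANNELS),
    shared_fraction: float = 0.8,
    amplitude: float = 1.0,
) -> np.ndarray:
    """One 30-s multichannel epoch block, shape (n_channels, fs·30)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if template is None:
        template = DEFAULT_TEMPLATES[stage]
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    n = int(round(fs * EPOCH_SECONDS))

    powers = dict(template.band_powers)
    k_amp_mult = k_rate_mult = 1.0
    if effect is not None:
        powers["beta"] = powers.get("beta", 0.0) * effect.beta_power
        powers["low"] = powers.get("low", 0.0) * effect.low_power
        if stage == "R":
            powers["sigma"] = powers.get("sigma", 0.0) * effect.rem_sigma_power
        k_amp_mult = effect.kcomplex_amp
        k_rate_mult = effect.kcomplex_rate

    total = sum(powers.values())
    if total <= 0:
        return np.zeros((n_channels, n))

    shared = _band_noise(rng, n, fs, powers)
    bg_sd = float(shared.std()) or 1.0

    dur_lo, dur_hi = template.event_duration
    for _ in range(rng.poisson(template.kcomplex_rate * k_rate_mult)):
        d = rng.uniform(dur_lo, dur_hi)
        _place_event(shared, make_kcomplex(
            d, fs, template.kcomplex_amp * k_amp_mult * bg_sd), rng)
    for _ in range(rng.poisson(template.spindle_rate)):
        d = rng.uniform(dur_lo, dur_hi)
        _place_event(shared, make_spindle(
            d, fs, template.spindle_amp * bg_sd), rng)

    block = np.empty((n_channels, n))
    w_shared = np.sqrt(shared_fraction)
    w_indep = np.sqrt(1.0 - shared_fraction)
    for c in range(n_channels):
        block[c] = w_shared * shared + w_indep * _band_noise(rng, n, fs, powers)
    return amplitude * block


def simulate_subject(
    meta: SubjectMeta, spec: CohortSpec, seed: int
) -> tuple[Recording, Hypnogram, float]:
    """One subject's full night: recording, hypnogram and SpO₂ scalar."""
    if meta.osa_class not in spec.effects:
        raise ValueError(f"no severity effect entry for {meta.osa_class!r}")
    rng = np.random.default_rng(seed)
    effect = spec.effects[meta.osa_class]
    hyp = simulate_hypnogram(spec.epochs_per_subject, spec.transition_matrix,
                             spec.initial_stage, rng)

    # fixed per-subject deviations: band-power jitter and overall gain
    jitter = {
        b: float(np.exp(rng.normal(0.0, spec.subject_jitter)))
        for b in GEN_BANDS
    }
    gain = spec.amplitude_uv * float(np.exp(rng.normal(0.0, 0.2)))
    templates = {
        s: replace(t, band_powers={b: p * jitter[b]
                                   for b, p in t.band_powers.items()})
        for s, t in spec.templates.items()
    }

    n = int(round(spec.fs * EPOCH_SECONDS))
    signals = np.empty((len(CANONICAL_CHANNELS), n * len(hyp)))
    for i, stage in enumerate(hyp.stages):
        signals[:, i * n:(i + 1) * n] = simulate_epoch(
            stage, templates[stage], spec.fs, rng, effect,
            shared_fraction=spec.shared_fraction, amplitude=gain,
        )
    rec = Recording(signals, spec.fs, CANONICAL_CHANNELS,
                    subject_id=meta.subject_id)

    mu, sd = spec.spo2_params[(meta.age_group, meta.osa_class)]
    spo2 = float(np.clip(rng.normal(mu, sd), 1e-6, 100.0))
    hyp = Hypnogram(hyp.stages, subject_id=meta.subject_id)
    return rec, hyp, spo2


def cohort_plan(spec: CohortSpec) -> list[tuple[SubjectMeta, int]]:
    """Deterministic (subject metadata, seed) list for a cohort spec.

    Per-subject seeds derive from the master seed, so any single subject
    can be regenerated independently of the rest of the cohort.
    """
    cells = [(a, c) for a in AGE_GROUPS for c in OSA_CLASSES
             if spec.n_in_cell(a, c) > 0]
    n_subjects = sum(spec.n_in_cell(a, c) for a, c in cells)
    sub_seeds = (np.random.SeedSequence(spec.seed).generate_state(n_subjects)
                 % (2**31))
    plan, i = [], 0
    for age_group, osa_class in cells:
        for j in range(spec.n_in_cell(age_group, osa_class)):
            sid = f"{age_group[0]}_{osa_class}_{j:03d}"
            plan.append((SubjectMeta(sid, age_group, osa_class),
                         int(sub_seeds[i])))
            i += 1
    return plan


def regenerate_subject(
    spec: CohortSpec, subject_id: str
) -> tuple[Recording, Hypnogram, float]:
    """Re-simulate one cohort subject without building the whole cohort."""
    for meta, seed in cohort_plan(spec):
        if meta.subject_id == subject_id:
            return simulate_subject(meta, spec, seed)
    raise KeyError(f"subject {subject_id!r} not in this cohort spec")


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Full in-memory cohort.

    Holds every recording's raw signal (≈29 MB per 100 epochs of six
    channels); for large cohorts prefer iterating :func:`cohort_plan` and
    discarding signals after feature extraction.
    """
    recordings, hypnograms, rows = {}, {}, []
    for meta, seed in cohort_plan(spec):
        rec, hyp, spo2 = simulate_subject(meta, spec, seed)
        recordings[meta.subject_id] = rec
        hypnograms[meta.subject_id] = hyp
        rows.append({"subject_id": meta.subject_id,
                     "age_group": meta.age_group,
                     "osa_class": meta.osa_class, "spo2": spo2})
    return Cohort(recordings, hypnograms, pd.DataFrame(rows))
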