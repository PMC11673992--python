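"""Synthetic music-session EEG generator.

Emulates the recording protocol the pipeline assumes: 19-channel, 250 Hz
sessions in which ten one-minute music tracks (five positive, five negative)
alternate with eight 15 s silent pauses (the neutral condition), about 720 s
in total.  Signals are produced by a linear instantaneous mixing model

    x(t) = A s(t) + pink(t) + white(t)

where the sources ``s`` are band-limited Gaussian processes whose variances
depend on the emotion class.  Each class owns one dominant source (default
variance ratio 4:1 against the shared background sources), so the planted
spatial structure is recoverable by CSP but not trivially separable.  The
neutral condition uses a distinct mid-band, lower-amplitude profile.

A cohort metadata table mirrors the screening questionnaire layout used for
subject validation (BDI depression score, 9-point SAM valence/arousal means,
control-question and motion-noise flags).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

POSITIVE, NEGATIVE, NEUTRAL = 0, 1, 2
CLASS_NAMES = {POSITIVE: "positive", NEGATIVE: "negative", NEUTRAL: "neutral"}

#: 10-20 montage of the 19 data channels (A1/A2 references excluded).
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

#: Track plan of a full session: P1..P5 / N1..N5 interleaved with 15 s
#: neutral pauses; 10 x 60 + 8 x 15 = 720 s.
DEFAULT_TRACK_PLAN: list[tuple[int, float]] = [
    (NEGATIVE, 60.0), (NEUTRAL, 15.0),
    (POSITIVE, 60.0), (NEUTRAL, 15.0),
    (NEGATIVE, 60.0), (NEUTRAL, 15.0),
    (POSITIVE, 60.0), (NEUTRAL, 15.0),
    (POSITIVE, 60.0), (NEUTRAL, 15.0),
    (NEGATIVE, 60.0), (NEUTRAL, 15.0),
    (NEGATIVE, 60.0), (NEUTRAL, 15.0),
    (POSITIVE, 60.0), (NEUTRAL, 15.0),
    (NEGATIVE, 60.0),
    (POSITIVE, 60.0),
]


@dataclass
class SimConfig:
    """Generator configuration.

    ``class_source_variances`` is a K x C matrix D: row i holds the variance
    of every source under class i.  ``band_profile`` gives each source's
    passband in Hz.  ``pink_scale`` / ``white_scale`` are noise standard
    deviations relative to a unit-variance source channel.
    """

    n_channels: int = 19
    fs: float = 250.0
    track_plan: list[tuple[int, float]] = field(
        default_factory=lambda: list(DEFAULT_TRACK_PLAN))
    n_subjects: int = 16
    n_classes: int = 3
    class_source_variances: np.ndarray | None = None
    band_profile: list[tuple[float, float]] | None = None
    pink_scale: float = 0.5
    white_scale: float = 0.2
    neutral_amplitude: float = 0.8
    separation: float = 4.0
    mixing_cond_max: float = 30.0
    subject_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d <= 0 for _, d in self.track_plan):
            raise ValueError("all track durations must be positive")
        if self.class_source_variances is None:
            self.class_source_variances = default_class_variances(
                self.n_classes, self.n_channels, self.separation)
        self.class_source_variances = np.asarray(
            self.class_source_variances, dtype=float)
        if np.any(self.class_source_variances <= 0):
            raise ValueError("source variances must be strictly positive")
        if self.band_profile is None:
            self.band_profile = default_band_profile(
                self.n_channels, self.n_classes)


@dataclass
class GroundTruth:
    """Planted parameters: mixing matrix, class variance table, timeline."""

    mixing: np.ndarray
    class_source_variances: np.ndarray
    timeline: list[tuple[float, float, int]] = field(default_factory=list)

    def unmixing(self) -> np.ndarray:
        return np.linalg.inv(self.mixing)


@dataclass
class SubjectRecord:
    """One row of the cohort screening table."""

    subject_id: int
    sex: str
    age: int
    bdi: float
    sam_val_pos: float | None
    sam_aro_pos: float | None
    sam_val_neg: float | None
    sam_aro_neg: float | None
    control_ok: bool = True
    motion_noise: bool = False
    retained: bool | None = None
    reason: str = ""


@dataclass
class EEGRecording:
    """Continuous multichannel signal with a class-label timeline."""

    data: np.ndarray                      # samples x channels, µV
    fs: float
    channel_labels: list[str]
    timeline: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be samples x channels")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count does not match label count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.fs,
                            list(self.channel_labels), list(self.timeline))


def default_class_variances(n_classes: int, n_sources: int,
                            separation: float = 4.0) -> np.ndarray:
    """Class-by-source variance table with one dominant source per class.

    Background sources have unit variance; class i's designated source
    (index i) carries ``separation`` times that, giving the planted CSP
    problem its contrast.
    """
    D = np.ones((n_classes, n_sources))
    for i in range(n_classes):
        D[i, i % n_sources] = separation
    return D


def default_band_profile(n_sources: int,
                         n_classes: int = 3) -> list[tuple[float, float]]:
    """Per-source passbands: the class-designated sources sit in alpha,
    beta and theta respectively; background sources are broadband."""
    bands = [(1.0, 45.0)] * n_sources
    class_bands = [(8.0, 13.0), (13.0, 30.0), (4.0, 8.0)]
    for i in range(min(n_classes, n_sources)):
        bands[i] = class_bands[i % len(class_bands)]
    return bands


def make_mixing_matrix(n_channels: int, seed: int,
                       cond_max: float = 30.0,
                       max_retries: int = 50) -> np.ndarray:
    """Random square mixing matrix with bounded condition number.

    Draws i.i.d. Gaussian matrices until the condition number is below
    ``cond_max``; deterministic for a fixed seed.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        A = rng.standard_normal((n_channels, n_channels))
        if np.linalg.cond(A) <= cond_max:
            return A
    raise RuntimeError(
        f"no mixing matrix with condition number <= {cond_max} "
        f"found in {max_retries} draws")


def make_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruth:
    seed = config.seed if seed is None else seed
    A = make_mixing_matrix(config.n_channels, seed, config.mixing_cond_max)
    return GroundTruth(mixing=A,
                       class_source_variances=config.class_source_variances)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float], numtaps: int = 251
                       ) -> np.ndarray:
    """Unit-variance Gaussian noise FIR-filtered to ``band``."""
    low, high = band
    pad = numtaps
    x = rng.standard_normal(n + 2 * pad)
    nyq = fs / 2.0
    high = min(high, nyq * 0.99)
    taps = sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    y = sps.lfilter(taps, 1.0, x)[pad + numtaps // 2: pad + numtaps // 2 + n]
    sd = y.std()
    if sd > 0:
        y = y / sd
    return y


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    y = np.fft.irfft(spec * scale, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_class_segment(class_id: int, duration_s: float,
                           ground_truth: GroundTruth, sim_config: SimConfig,
                           seed: int) -> np.ndarray:
    """Simulate one segment of a given emotion class.

    Returns a T x C array with T = duration_s * fs; sources are band-limited
    Gaussian with the class-specific variances, mixed by the planted matrix,
    plus 1/f and white sensor noise.
    """
    K = ground_truth.class_source_variances.shape[0]
    if not 0 <= class_id < K:
        raise ValueError(f"unknown class_id {class_id} (K={K})")
    n = duration_s * sim_config.fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration_s * fs must be integral")
    n = int(round(n))
    C = sim_config.n_channels
    rng = np.random.default_rng(seed)
    D = ground_truth.class_source_variances[class_id]
    S = np.empty((n, C))
    for k in range(C):
        S[:, k] = _bandlimited_noise(rng, n, sim_config.fs,
                                     sim_config.band_profile[k])
        S[:, k] *= np.sqrt(D[k])
    X = S @ ground_truth.mixing.T
    if sim_config.pink_scale > 0:
        for c in range(C):
            X[:, c] += sim_config.pink_scale * _pink_noise(rng, n)
    if sim_config.white_scale > 0:
        X += sim_config.white_scale * rng.standard_normal((n, C))
    if class_id == NEUTRAL:
        X *= sim_config.neutral_amplitude
    return X


def simulate_session(sim_config: SimConfig, ground_truth: GroundTruth,
                     seed: int) -> EEGRecording:
    """Concatenate class segments per the track plan into one recording."""
    if not sim_config.track_plan:
        raise ValueError("track_plan must be non-empty")
    segments = []
    timeline: list[tuple[float, float, int]] = []
    t = 0.0
    rng = np.random.default_rng(seed)
    for class_id, dur in sim_config.track_plan:
        seg_seed = int(rng.integers(0, 2**31 - 1))
        segments.append(simulate_class_segment(
            class_id, dur, ground_truth, sim_config, seg_seed))
        timeline.append((t, t + dur, class_id))
        t += dur
    data = np.vstack(segments)
    labels = CHANNELS_1020[:sim_config.n_channels]
    if len(labels) < sim_config.n_channels:
        labels = labels + [f"EEG{i}" for i in
                           range(len(labels), sim_config.n_channels)]
    ground_truth.timeline = timeline
    return EEGRecording(data=data, fs=sim_config.fs, channel_labels=labels,
                        timeline=timeline)


def add_noise_snr(signal: np.ndarray, snr_db: float, seed: int,
                  band: tuple[float, float] | None = None,
                  fs: float | None = None) -> np.ndarray:
    """Add Gaussian noise at a prescribed SNR in dB.

    Noise power is scaled so 10*log10(P_signal / P_noise) = snr_db, with
    power measured over all samples and channels.  ``snr_db = inf`` is the
    no-noise identity.  With ``band`` (and ``fs``) the white noise is
    FIR-filtered to that passband before scaling — the epoch-level
    equivalent of corrupting the raw recording and re-running the
    band-pass preprocessing.
    """
    signal = np.asarray(signal, dtype=float)
    if np.isinf(snr_db) and snr_db > 0:
        return signal.copy()
    p_sig = float(np.mean(signal ** 2))
    if p_sig == 0:
        raise ValueError("SNR undefined for an all-zero signal")
    p_noise = p_sig / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.shape)
    if band is not None:
        if fs is None:
            raise ValueError("band-limited noise requires fs")
        flat = noise if noise.ndim == 2 else noise[:, None]
        filtered = np.empty_like(flat)
        numtaps = min(251, 2 * (flat.shape[0] // 2) - 1)
        low, high = band
        taps = sps.firwin(numtaps, [low, min(high, 0.99 * fs / 2)],
                          pass_zero=False, fs=fs)
        pad = min(3 * numtaps, flat.shape[0] - 1)
        filtered = sps.filtfilt(taps, 1.0, flat, axis=0, padlen=pad)
        noise = filtered.reshape(noise.shape)
    noise *= np.sqrt(p_noise / max(np.mean(noise ** 2), 1e-300))
    return signal + noise


# ---------------------------------------------------------------------------
# Cohort metadata

_SCREENING_TABLE_ROWS = [
    # (subject, sex, age, bdi, vp, ap, vn, an, control_ok, motion)
    (1, "M", 25, 16, 9.0, 9.0, 1.8, 1.0, True, False),
    (2, "M", 24, 22, 6.8, 6.2, 3.6, 2.0, True, False),
    (3, "F", 27, 19, 6.2, 7.4, 4.2, 4.6, False, False),
    (4, "M", 24, 4, 7.4, 7.6, 2.4, 2.6, True, False),
    (5, "M", 24, 0, 5.8, 5.0, 4.4, 5.6, False, False),
    (6, "M", 28, 10, 5.6, 5.4, 2.0, 1.6, True, False),
    (7, "M", 28, 13, 7.2, 7.4, 3.8, 3.8, True, False),
    (8, "M", 20, 19, 7.8, 7.4, 2.8, 3.0, True, False),
    (9, "M", 26, 9, 7.4, 7.0, 3.4, 5.4, True, False),
    (10, "F", 23, 9, 6.8, 6.6, 3.8, 3.2, True, False),
    (11, "F", 25, 22, 7.8, 8.0, 4.5, 3.0, True, False),
    (12, "F", 27, 1, 8.6, 8.6, 2.0, 1.2, True, False),
    (13, "F", 29, 9, 6.0, 6.0, 2.0, 1.2, True, False),
    (14, "M", 26, 8, 8.0, 8.0, 1.8, 1.8, True, False),
    (15, "F", 25, 12, None, None, None, None, True, True),
    (16, "M", 27, 0, 7.4, 8.0, 1.8, 2.0, True, False),
]


def reference_cohort() -> list[SubjectRecord]:
    """The canonical 16-subject screening table used in the worked examples
    (seven of these subjects survive the documented screening rules)."""
    return [SubjectRecord(subject_id=s, sex=sex, age=age, bdi=bdi,
                          sam_val_pos=vp, sam_aro_pos=ap,
                          sam_val_neg=vn, sam_aro_neg=an,
                          control_ok=ok, motion_noise=mn)
            for (s, sex, age, bdi, vp, ap, vn, an, ok, mn)
            in _SCREENING_TABLE_ROWS]


def simulate_cohort_metadata(n_subjects: int, seed: int
                             ) -> list[SubjectRecord]:
    """Draw a random cohort spanning retain/exclude regimes.

    BDI is drawn over 0..25 so some subjects exceed the clinical cutoff of
    21; SAM means straddle the low (<3) / high (>=6) regimes; a small
    fraction of subjects fail the control question or show motion noise.
    """
    rng = np.random.default_rng(seed)
    records = []
    for s in range(1, n_subjects + 1):
        motion = bool(rng.random() < 0.08)
        control = bool(rng.random() > 0.12)
        bdi = float(rng.integers(0, 26))
        if motion:
            vp = ap = vn = an = None
        else:
            vp = float(np.clip(rng.normal(7.0, 1.5), 1, 9).round(1))
            ap = float(np.clip(rng.normal(7.0, 1.5), 1, 9).round(1))
            vn = float(np.clip(rng.normal(3.0, 1.3), 1, 9).round(1))
            an = float(np.clip(rng.normal(2.5, 1.5), 1, 9).round(1))
        records.append(SubjectRecord(
            subject_id=s,
            sex="F" if rng.random() < 0.4 else "M",
            age=int(rng.integers(20, 30)),
            bdi=bdi,
            sam_val_pos=vp, sam_aro_pos=ap,
            sam_val_neg=vn, sam_aro_neg=an,
            control_ok=control, motion_noise=motion))
    return records


def ground_truth_to_json(gt: GroundTruth) -> str:
    return json.dumps({
        "mixing": gt.mixing.tolist(),
        "class_source_variances": gt.class_source_variances.tolist(),
        "timeline": [[s, e, int(c)] for s, e, c in gt.timeline],
    })


def ground_truth_from_json(text: str) -> GroundTruth:
    d = json.loads(text)
    return GroundTruth(
        mixing=np.asarray(d["mixing"]),
        class_source_variances=np.asarray(d["class_source_variances"]),
        timeline=[(s, e, int(c)) for s, e, c in d["timeline"]])
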