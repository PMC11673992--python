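"""Preprocessing: filtering, screening, trimming, segmentation, bands.

The chain mirrors a standard music-session emotion protocol: 50 Hz notch,
0.5-45 Hz zero-phase FIR band-pass (order 800), optional ICA-based artifact
rejection, removal of the first and last 10 s of each music track, merging
per-class segments into one continuous signal, and overlapping rectangular
windowing (3 s windows, 70% overlap for the music classes; the neutral
class overlap is raised until the class counts balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import EEGRecording, SubjectRecord, NEUTRAL


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high <= fs / 2:
            raise ValueError(
                f"band {self.name}: need 0 < low < high <= fs/2, "
                f"got ({self.low}, {self.high}) at fs={fs}")


#: Canonical EEG bands used throughout.
CANONICAL_BANDS = [
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
]

ALL_BAND = BandDefinition("all", 0.5, 45.0)

#: Finer beta/gamma sub-bands.
SUB_BANDS = [
    BandDefinition("beta1", 13.0, 21.0),
    BandDefinition("beta2", 21.0, 30.0),
    BandDefinition("gamma1", 30.0, 38.0),
    BandDefinition("gamma2", 38.0, 45.0),
]


@dataclass
class EpochSet:
    """Stack of fixed-length epochs with class labels.

    ``epochs`` is n x T x C; ``labels`` the per-epoch class; ``subject_ids``
    the originating subject; ``band_tag`` names the frequency band carried.
    """

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray | None = None
    band_tag: str = "all"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n x T x C")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels/epochs length mismatch")
        if self.subject_ids is None:
            self.subject_ids = np.zeros(len(self.epochs), dtype=int)
        else:
            self.subject_ids = np.asarray(self.subject_ids)

    def __len__(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# Filtering

def notch_filter(recording: EEGRecording, f0: float = 50.0,
                 q: float = 30.0) -> EEGRecording:
    """Zero-phase IIR notch at ``f0`` (power-line removal)."""
    if f0 >= recording.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = sps.iirnotch(f0, q, fs=recording.fs)
    out = recording.copy()
    out.data = sps.filtfilt(b, a, recording.data, axis=0)
    return out


def design_fir(low: float, high: float, fs: float,
               order: int = 800) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) band-pass taps."""
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={fs}")
    if order < 2:
        raise ValueError("order must be >= 2")
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # odd taps -> type-I filter, valid at any band edge
    return sps.firwin(numtaps, [low, high], pass_zero=False,
                      window="hamming", fs=fs)


def bandpass_fir(recording: EEGRecording, low: float, high: float,
                 order: int = 800) -> EEGRecording:
    """Zero-phase FIR band-pass (forward-backward application).

    Forward-backward filtering squares the magnitude response, so the
    half-power point of the applied filter sits at the design's -3 dB
    frequency; edges of the windowed-sinc design sit at -6 dB, i.e. the
    applied -6 dB points coincide with the requested band edges.
    """
    taps = design_fir(low, high, recording.fs, order)
    out = recording.copy()
    padlen = min(3 * len(taps), recording.n_samples - 1)
    out.data = sps.filtfilt(taps, 1.0, recording.data, axis=0,
                            padlen=padlen)
    return out


def decompose_bands(recording: EEGRecording,
                    bands: list[BandDefinition],
                    order: int = 800) -> dict[str, EEGRecording]:
    """One band-pass filtered copy of the recording per band."""
    out = {}
    for band in bands:
        band.validate(recording.fs)
        out[band.name] = bandpass_fir(recording, band.low, band.high, order)
    return out


# ---------------------------------------------------------------------------
# Subject screening

def screen_subjects(records: list[SubjectRecord], bdi_max: float = 21.0,
                    sam_low: float = 3.0, sam_high: float = 6.0
                    ) -> tuple[list[SubjectRecord], dict[int, str]]:
    """Apply the questionnaire screening rules.

    Exclusions, in precedence order: motion noise; failed control question;
    BDI strictly above ``bdi_max``; failed positive induction (valence or
    arousal below the high regime, taken as >= ``sam_high``); failed
    negative induction (valence not strictly below ``sam_low``).  Returns
    the retained records and a per-subject reason map; the records are
    annotated in place.
    """
    if not sam_low < sam_high:
        raise ValueError("need sam_low < sam_high")
    retained = []
    reasons: dict[int, str] = {}
    for r in records:
        reason = ""
        if r.motion_noise:
            reason = "motion noise"
        elif not r.control_ok:
            reason = "mismatch of the control question in the SAM test"
        elif r.bdi is None:
            raise ValueError(f"subject {r.subject_id}: missing BDI")
        elif r.bdi > bdi_max:
            reason = f"Beck depression ({bdi_max:g} < {r.bdi:g})"
        else:
            for f in ("sam_val_pos", "sam_aro_pos", "sam_val_neg"):
                if getattr(r, f) is None:
                    raise ValueError(
                        f"subject {r.subject_id}: missing field {f}")
            if r.sam_val_pos < sam_high or r.sam_aro_pos < sam_high:
                reason = "lack of induction in the positive emotional class"
            elif not r.sam_val_neg < sam_low:
                reason = "lack of induction in the negative emotional class"
        r.retained = reason == ""
        r.reason = reason or "-"
        reasons[r.subject_id] = r.reason
        if r.retained:
            retained.append(r)
    return retained, reasons


# ---------------------------------------------------------------------------
# Trimming / merging / segmentation

def trim_head_tail(epoch_signal: np.ndarray, fs: float, head_s: float,
                   tail_s: float) -> np.ndarray:
    """Drop the first ``head_s`` and last ``tail_s`` seconds."""
    n = epoch_signal.shape[0]
    h = int(round(head_s * fs))
    t = int(round(tail_s * fs))
    if h + t >= n:
        raise ValueError(
            f"cannot trim {head_s}+{tail_s} s from {n / fs:g} s of signal")
    return epoch_signal[h:n - t if t else n]


def merge_class_signal(recording: EEGRecording, class_id: int,
                       head_s: float = 0.0, tail_s: float = 0.0
                       ) -> np.ndarray:
    """Concatenate all (trimmed) timeline segments of one class."""
    pieces = []
    for start, end, cls in recording.timeline:
        if cls != class_id:
            continue
        i0 = int(round(start * recording.fs))
        i1 = int(round(end * recording.fs))
        seg = recording.data[i0:i1]
        if head_s or tail_s:
            seg = trim_head_tail(seg, recording.fs, head_s, tail_s)
        pieces.append(seg)
    if not pieces:
        raise ValueError(f"no timeline segments of class {class_id}")
    return np.vstack(pieces)


def segment_overlap(signal: np.ndarray, fs: float, win_s: float,
                    overlap_frac: float) -> np.ndarray:
    """Rectangular windows of L = win_s*fs samples with fractional overlap.

    Step = round(L * (1 - overlap_frac)); windows are half-open
    [start, start+L); trailing partial windows are discarded, so the count
    is floor((N - L) / step) + 1.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    N = signal.shape[0]
    L = int(round(win_s * fs))
    if L > N:
        raise ValueError(f"window of {L} samples exceeds signal of {N}")
    step = max(1, int(round(L * (1.0 - overlap_frac))))
    starts = np.arange(0, N - L + 1, step)
    return np.stack([signal[s:s + L] for s in starts])


def n_overlap_windows(n_samples: int, win_len: int, step: int) -> int:
    if win_len > n_samples:
        return 0
    return (n_samples - win_len) // step + 1


def solve_overlap_for_count(signal_len: int, win_len: int,
                            target_count: int) -> float:
    """Smallest overlap fraction giving at least ``target_count`` windows.

    Searches over integer steps (largest step whose count reaches the
    target) and returns 1 - step/L.  Used to raise the neutral-class
    overlap until its epoch count matches the music classes.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if win_len > signal_len:
        raise ValueError("window longer than signal")
    if target_count == 1:
        return 0.0
    # count(step) is non-increasing in step; find the largest feasible step
    for step in range(win_len, 0, -1):
        if n_overlap_windows(signal_len, win_len, step) >= target_count:
            return 1.0 - step / win_len
    raise ValueError(
        f"cannot reach {target_count} windows from {signal_len} samples")


def build_epochs(recording: EEGRecording, win_s: float = 3.0,
                 overlap_frac: float = 0.70, head_s: float = 10.0,
                 tail_s: float = 10.0, classes: tuple[int, ...] = (0, 1, 2),
                 balance: bool = True, subject_id: int = 0,
                 band_tag: str = "all") -> EpochSet:
    """Full segmentation stage for one recording.

    Music-class tracks are trimmed and merged, then windowed at
    ``overlap_frac``; the neutral class (untrimmed pauses) is windowed at
    the overlap that brings its count up to the music-class count when
    ``balance`` is set.
    """
    L = int(round(win_s * recording.fs))
    music_counts = {}
    epochs, labels = [], []
    for cls in classes:
        if cls == NEUTRAL:
            continue
        merged = merge_class_signal(recording, cls, head_s, tail_s)
        wins = segment_overlap(merged, recording.fs, win_s, overlap_frac)
        music_counts[cls] = len(wins)
        epochs.append(wins)
        labels.append(np.full(len(wins), cls))
    if NEUTRAL in classes:
        merged = merge_class_signal(recording, NEUTRAL, 0.0, 0.0)
        frac = overlap_frac
        if balance and music_counts:
            target = max(music_counts.values())
            frac = max(frac, solve_overlap_for_count(
                merged.shape[0], L, target))
        wins = segment_overlap(merged, recording.fs, win_s, frac)
        if balance and music_counts:
            wins = wins[:max(music_counts.values())]
        epochs.append(wins)
        labels.append(np.full(len(wins), NEUTRAL))
    ep = np.concatenate(epochs)
    lab = np.concatenate(labels)
    return EpochSet(epochs=ep, labels=lab,
                    subject_ids=np.full(len(ep), subject_id),
                    band_tag=band_tag)


# ---------------------------------------------------------------------------
# Automated artifact rejection (surrogate for manual ICA inspection)

def reject_artifact_components(recording: EEGRecording,
                               kurtosis_z: float = 3.0,
                               variance_ratio: float = 3.0,
                               seed: int = 0) -> EEGRecording:
    """ICA decomposition with automatic component rejection.

    Components whose kurtosis is an outlier (z-score above ``kurtosis_z``
    across components) or whose variance exceeds ``variance_ratio`` times
    the median component variance are zeroed before reconstruction.  This
    automates the usual visual inspection; it is off by default in the
    pipeline since the synthetic generator plants no artifacts.
    """
    from scipy.stats import kurtosis as _kurt
    from sklearn.decomposition import FastICA

    X = recording.data
    if X.shape[1] < 2:
        raise ValueError("ICA needs at least 2 channels")
    if np.linalg.matrix_rank(np.cov(X.T)) < X.shape[1]:
        raise ValueError("rank-deficient input")
    ica = FastICA(n_components=X.shape[1], random_state=seed,
                  whiten="unit-variance", max_iter=500)
    S = ica.fit_transform(X)
    k = _kurt(S, axis=0, fisher=True)
    kz = (k - k.mean()) / (k.std() + 1e-12)
    v = S.var(axis=0) * (ica.mixing_ ** 2).sum(axis=0)
    bad = (kz > kurtosis_z) | (v > variance_ratio * np.median(v))
    S_clean = S.copy()
    S_clean[:, bad] = 0.0
    out = recording.copy()
    out.data = ica.inverse_transform(S_clean)
    return out
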