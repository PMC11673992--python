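"""Readers and writers for on-disk artifacts.

Recordings travel either as EDF (interchange with standard EEG tooling;
16-bit quantized) or as a compressed ``.npz`` container with a JSON
sidecar carrying the timeline and, for synthetic sessions, the planted
ground truth (lossless round trip).  Epoch sets, cohort metadata, feature
tables and fitted pipelines have their own npz/CSV forms.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .ensemble import CAEStackingClassifier, ConvAutoencoder, DenseHead
from .mccsp import MCCSP
from .preprocess import EpochSet
from .simulate import (EEGRecording, GroundTruth, SubjectRecord,
                       ground_truth_from_json, ground_truth_to_json)

REFERENCE_LABELS = {"A1", "A2"}


# ---------------------------------------------------------------------------
# EDF

def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as plain EDF (one-second records, int16).

    Physical scaling is per-channel symmetric around zero; the trailing
    partial second, if any, is zero-padded (the sidecar keeps the true
    sample count).
    """
    path = Path(path)
    data = recording.data
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_samples, n_ch = data.shape
    n_rec = -(-n_samples // spr)
    padded = np.zeros((n_rec * spr, n_ch))
    padded[:n_samples] = data

    phys_max = np.maximum(np.abs(padded).max(axis=0), 1e-6)
    dig_max, dig_min = 32767, -32768
    scaled = np.clip(padded / phys_max, -1, 1) * dig_max
    digital = np.round(scaled).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        [pad(lab, 16) for lab in recording.channel_labels],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.writelines(block)
        for r in range(n_rec):
            chunk = digital[r * spr:(r + 1) * spr]
            fh.write(chunk.T.tobytes())
    _write_sidecar(path, recording, n_samples=n_samples)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, recording: EEGRecording,
                   ground_truth: GroundTruth | None = None,
                   n_samples: int | None = None) -> None:
    payload = {
        "timeline": [[s, e, int(c)] for s, e, c in recording.timeline],
        "fs": recording.fs,
        "n_samples": n_samples or recording.n_samples,
    }
    if ground_truth is not None:
        payload["ground_truth"] = json.loads(ground_truth_to_json(
            ground_truth))
    _sidecar_path(Path(path)).write_text(json.dumps(payload))


def read_edf(path: str | Path, drop_reference: bool = True
             ) -> EEGRecording:
    """Read an EDF through MNE; data returned in µV.

    Reference channels (A1/A2) are dropped by default so a 21-channel file
    yields the 19 data channels.  A timeline sidecar is honoured when
    present.
    """
    import mne
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"malformed EDF {path}: {exc}") from exc
    labels = list(raw.ch_names)
    data = raw.get_data().T * 1e6
    if drop_reference:
        keep = [i for i, lab in enumerate(labels)
                if lab not in REFERENCE_LABELS]
        data = data[:, keep]
        labels = [labels[i] for i in keep]
    timeline = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        timeline = [(s, e, int(c)) for s, e, c in meta.get("timeline", [])]
        n = meta.get("n_samples")
        if n is not None:
            data = data[:n]
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=labels, timeline=timeline)


# ---------------------------------------------------------------------------
# Array container

def write_recording_npz(recording: EEGRecording, path: str | Path,
                        ground_truth: GroundTruth | None = None) -> None:
    path = Path(path)
    np.savez_compressed(
        path, data=recording.data, fs=recording.fs,
        channel_labels=np.array(recording.channel_labels))
    _write_sidecar(path, recording, ground_truth)


def read_recording_npz(path: str | Path
                       ) -> tuple[EEGRecording, GroundTruth | None]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        data = z["data"]
        fs = float(z["fs"])
        labels = [str(x) for x in z["channel_labels"]]
    timeline, gt = [], None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        timeline = [(s, e, int(c)) for s, e, c in meta.get("timeline", [])]
        if "ground_truth" in meta:
            gt = ground_truth_from_json(json.dumps(meta["ground_truth"]))
    return EEGRecording(data=data, fs=fs, channel_labels=labels,
                        timeline=timeline), gt


def read_recording(path: str | Path) -> EEGRecording:
    """Dispatch on extension: ``.edf`` or the npz container."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return read_recording_npz(path)[0]


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    np.savez_compressed(Path(path), epochs=epochs.epochs,
                        labels=epochs.labels,
                        subject_ids=epochs.subject_ids,
                        band_tag=np.array(epochs.band_tag))


def read_epochs(path: str | Path) -> EpochSet:
    with np.load(Path(path), allow_pickle=False) as z:
        return EpochSet(epochs=z["epochs"], labels=z["labels"],
                        subject_ids=z["subject_ids"],
                        band_tag=str(z["band_tag"]))


# ---------------------------------------------------------------------------
# Metadata tables

def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_cohort_csv(records: list[SubjectRecord],
                     path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fitted-pipeline serialization

def save_pipeline(mccsp: MCCSP, clf: CAEStackingClassifier,
                  path: str | Path) -> None:
    """Persist MCCSP filters and all network weights into one npz."""
    arrays: dict[str, np.ndarray] = {
        "mccsp_filters": mccsp.filters_,
        "mccsp_classes": mccsp.classes_,
        "clf_classes": clf.classes_,
        "scale": np.array([clf.scale_min_, clf.scale_max_]),
        "feat_mean": clf.feat_mean_,
        "feat_std": clf.feat_std_,
        "input_shape": np.array(clf.branches_[0].input_shape),
    }
    manifest = {
        "mccsp": mccsp.get_params(),
        "clf": clf.get_params(),
        "n_branches": len(clf.branches_),
    }
    for b, branch in enumerate(clf.branches_):
        for li, layer in enumerate(branch.net.layers):
            for k, v in layer.params.items():
                arrays[f"branch{b}_layer{li}_{k}"] = v
    for li, layer in enumerate(clf.head_.net.layers):
        for k, v in layer.params.items():
            arrays[f"head_layer{li}_{k}"] = v
    arrays["manifest"] = np.array(json.dumps(manifest))
    np.savez_compressed(Path(path), **arrays)


def load_pipeline(path: str | Path) -> tuple[MCCSP, CAEStackingClassifier]:
    with np.load(Path(path), allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        mccsp = MCCSP(**manifest["mccsp"])
        mccsp.filters_ = z["mccsp_filters"]
        mccsp.classes_ = z["mccsp_classes"]
        mccsp.bank_ = None  # filters are enough for transform
        clf = CAEStackingClassifier(**manifest["clf"])
        clf.classes_ = z["clf_classes"]
        clf.scale_min_, clf.scale_max_ = map(float, z["scale"])
        clf.feat_mean_ = z["feat_mean"]
        clf.feat_std_ = z["feat_std"]
        shape = tuple(int(x) for x in z["input_shape"])
        clf.branches_ = []
        for b in range(manifest["n_branches"]):
            branch = ConvAutoencoder(shape, manifest["clf"]["activation"])
            for li, layer in enumerate(branch.net.layers):
                for k in list(layer.params):
                    layer.params[k] = z[f"branch{b}_layer{li}_{k}"].astype(
                        nn.DTYPE)
            clf.branches_.append(branch)
        n_in = manifest["n_branches"] * clf.branches_[0].flatten_len
        head = DenseHead(n_in, len(clf.classes_))
        for li, layer in enumerate(head.net.layers):
            for k in list(layer.params):
                layer.params[k] = z[f"head_layer{li}_{k}"].astype(nn.DTYPE)
        clf.head_ = head
    return mccsp, clf
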