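"""Metrics and experiment grids.

All scalar metrics are reported in percent: accuracy, macro-averaged
precision/recall/F1, and Cohen's kappa computed from the multi-class
confusion matrix.  Experiment drivers cover the noise-robustness sweep
(white noise added to held-out epochs only, model fixed), the per-band
sweep (full pipeline re-run per frequency band) and the repeated-runs
protocol (mean +/- std of test accuracy over retrains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import (cohen_kappa_score, confusion_matrix,
                             precision_recall_fscore_support)

from .preprocess import BandDefinition
from .simulate import add_noise_snr

#: SNR grid of the robustness sweep, in dB (worst first).
DEFAULT_SNR_GRID = (-4.0, 0.0, 1.0, 10.0, 20.0)


@dataclass
class EvalReport:
    """Metrics for one experiment condition (percent scale)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    confusion: np.ndarray
    labels: np.ndarray
    condition: dict = field(default_factory=dict)
    roc: dict | None = None

    def as_row(self) -> dict:
        row = {"accuracy": self.accuracy, "precision": self.precision,
               "recall": self.recall, "f1": self.f1, "kappa": self.kappa}
        row.update(self.condition)
        return row


def classification_metrics(y_true: Sequence, y_pred: Sequence,
                           labels: Sequence | None = None,
                           condition: dict | None = None) -> EvalReport:
    """Accuracy, macro precision/recall/F1 and Cohen's kappa, in percent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    labels = (np.unique(np.concatenate([y_true, y_pred]))
              if labels is None else np.asarray(labels))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    acc = float(np.trace(cm) / cm.sum())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=labels))
    return EvalReport(accuracy=100 * acc, precision=100 * float(prec),
                      recall=100 * float(rec), f1=100 * float(f1),
                      kappa=100 * kappa, confusion=cm, labels=labels,
                      condition=condition or {})


def metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    """Recompute the scalar metrics from a stored confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    acc = np.trace(cm) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.nan_to_num(np.diag(cm) / cm.sum(axis=0))
        rec = np.nan_to_num(np.diag(cm) / cm.sum(axis=1))
        f1 = np.nan_to_num(2 * prec * rec / (prec + rec))
    p_o = acc
    p_e = float((cm.sum(axis=0) * cm.sum(axis=1)).sum() / n ** 2)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    return {"accuracy": 100 * float(acc),
            "precision": 100 * float(prec.mean()),
            "recall": 100 * float(rec.mean()),
            "f1": 100 * float(f1.mean()),
            "kappa": 100 * float(kappa)}


def roc_ovr(y_true: Sequence, probabilities: np.ndarray,
            labels: Sequence | None = None) -> dict:
    """One-vs-rest ROC curves by threshold sweep, AUC by trapezoid rule."""
    y_true = np.asarray(y_true)
    P = np.asarray(probabilities, dtype=float)
    if P.min() < 0 or P.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    labels = np.unique(y_true) if labels is None else np.asarray(labels)
    out = {}
    for k, cls in enumerate(labels):
        pos = (y_true == cls).astype(int)
        scores = P[:, k]
        order = np.argsort(-scores, kind="stable")
        pos_sorted = pos[order]
        tps = np.cumsum(pos_sorted)
        fps = np.cumsum(1 - pos_sorted)
        # keep one point per distinct threshold
        distinct = np.r_[np.where(np.diff(scores[order]) != 0)[0],
                         len(scores) - 1]
        tpr = np.r_[0.0, tps[distinct] / max(pos.sum(), 1)]
        fpr = np.r_[0.0, fps[distinct] / max((1 - pos).sum(), 1)]
        auc = float(np.trapezoid(tpr, fpr))
        out[cls] = {"fpr": fpr, "tpr": tpr, "auc": auc}
    return out


# ---------------------------------------------------------------------------
# Experiment grids

def noise_sweep(predict_fn: Callable[[np.ndarray], np.ndarray],
                epochs: np.ndarray, labels: np.ndarray,
                snr_list: Sequence[float] = DEFAULT_SNR_GRID,
                seed: int = 0,
                band: tuple[float, float] | None = None,
                fs: float | None = None) -> list[EvalReport]:
    """Robustness of a fixed model to additive noise.

    Noise is injected per epoch at each SNR into the held-out data only;
    the model is not retrained.  When the pipeline band-passes its inputs,
    pass ``band``/``fs`` so the injected noise is filtered the same way
    the raw recording would have been — corrupting band-limited epochs
    with full-band white noise probes an input the preprocessing chain
    can never produce.
    """
    epochs = np.asarray(epochs)
    reports = []
    for snr in snr_list:
        rng = np.random.default_rng(seed)
        noisy = np.stack([
            add_noise_snr(e, snr, seed=int(rng.integers(0, 2**31 - 1)),
                          band=band, fs=fs)
            for e in epochs])
        y_pred = predict_fn(noisy)
        reports.append(classification_metrics(
            labels, y_pred, condition={"snr_db": float(snr)}))
    return reports


def band_sweep(run_for_band: Callable[[BandDefinition], EvalReport],
               band_sets: Sequence[BandDefinition]) -> list[EvalReport]:
    """Re-run the full pipeline once per frequency band."""
    reports = []
    for band in band_sets:
        rep = run_for_band(band)
        rep.condition.setdefault("band", band.name)
        reports.append(rep)
    return reports


def repeated_runs(run_fn: Callable[[int], float],
                  seeds: Sequence[int]) -> tuple[float, float, list[float]]:
    """Mean and population std of test accuracy over reseeded retrains."""
    accs = [float(run_fn(int(s))) for s in seeds]
    return float(np.mean(accs)), float(np.std(accs)), accs
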