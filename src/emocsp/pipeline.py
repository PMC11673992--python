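"""End-to-end experiment drivers tying the stages together.

`run_experiment` takes a segmented :class:`EpochSet`, splits it 70/15/15,
fits MCCSP on the training epochs, trains the autoencoder stacking
ensemble and reports test metrics.  `run_baseline_experiment` does the
same with the hand-crafted-feature voting ensemble.  `build_cohort_epochs`
produces the default synthetic study: a screened cohort, one session per
retained subject, and balanced 3 s / 70%-overlap epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import (BaselineVotingEnsemble, KruskalWallisSelector,
                       extract_feature_matrix)
from .ensemble import CAEStackingClassifier, SplitPlan
from .evaluate import EvalReport, classification_metrics, roc_ovr
from .mccsp import MCCSP
from .preprocess import EpochSet, build_epochs
from .simulate import (SimConfig, make_ground_truth, simulate_cohort_metadata,
                       simulate_session)
from .preprocess import screen_subjects


@dataclass
class EmotionPipeline:
    """A fitted spatial-filter + classifier pair operating on raw epochs."""

    mccsp: MCCSP
    classifier: CAEStackingClassifier

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(self.mccsp.transform(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(self.mccsp.transform(X))


@dataclass
class ExperimentResult:
    report: EvalReport
    pipeline: EmotionPipeline
    split: tuple[np.ndarray, np.ndarray, np.ndarray]
    test_epochs: np.ndarray
    test_labels: np.ndarray


def run_experiment(epochs: EpochSet, split_plan: SplitPlan | None = None,
                   mccsp_params: dict | None = None,
                   clf_params: dict | None = None,
                   seed: int = 0, with_roc: bool = False
                   ) -> ExperimentResult:
    """Split, fit MCCSP + ensemble on the training set, score the test set."""
    split_plan = split_plan or SplitPlan(seed=seed)
    tr, va, te = split_plan.split_indices(epochs.labels, epochs.subject_ids)
    X, y = epochs.epochs, epochs.labels
    mccsp = MCCSP(**(mccsp_params or {})).fit(X[tr], y[tr])
    Ztr, Zva, Zte = (mccsp.transform(X[i]) for i in (tr, va, te))
    clf = CAEStackingClassifier(
        **{"random_state": seed, **(clf_params or {})})
    clf.fit(Ztr, y[tr], validation_data=(Zva, y[va]))
    proba = clf.predict_proba(Zte)
    y_pred = clf.classes_[proba.argmax(axis=1)]
    report = classification_metrics(
        y[te], y_pred, labels=clf.classes_,
        condition={"band": epochs.band_tag, "n_test": len(te)})
    if with_roc:
        report.roc = roc_ovr(y[te], proba, labels=clf.classes_)
    return ExperimentResult(report=report,
                            pipeline=EmotionPipeline(mccsp, clf),
                            split=(tr, va, te),
                            test_epochs=X[te], test_labels=y[te])


def run_baseline_experiment(epochs: EpochSet,
                            split_plan: SplitPlan | None = None,
                            mccsp_params: dict | None = None,
                            alpha: float = 0.05, seed: int = 0
                            ) -> EvalReport:
    """Same protocol with the 32-feature KW-screened voting ensemble."""
    split_plan = split_plan or SplitPlan(seed=seed)
    tr, va, te = split_plan.split_indices(epochs.labels, epochs.subject_ids)
    X, y = epochs.epochs, epochs.labels
    mccsp = MCCSP(**(mccsp_params or {})).fit(X[tr], y[tr])
    Ftr = extract_feature_matrix(mccsp.transform(X[tr]))
    Fte = extract_feature_matrix(mccsp.transform(X[te]))
    sel = KruskalWallisSelector(alpha=alpha).fit(Ftr, y[tr])
    model = BaselineVotingEnsemble(random_state=seed).fit(
        sel.transform(Ftr), y[tr])
    y_pred = model.predict(sel.transform(Fte))
    return classification_metrics(
        y[te], y_pred, condition={"band": epochs.band_tag,
                                  "method": "baseline", "n_test": len(te)})


def build_cohort_epochs(config: SimConfig | None = None, seed: int = 0,
                        n_retained: int | None = 7,
                        win_s: float = 3.0, overlap_frac: float = 0.70,
                        head_s: float = 10.0, tail_s: float = 10.0,
                        band: tuple[float, float] = (0.5, 45.0),
                        notch_hz: float = 50.0, fir_order: int = 800
                        ) -> tuple[EpochSet, list]:
    """Simulate a screened cohort and return its pooled, balanced epochs.

    One session is generated per retained subject (all sharing the planted
    mixing matrix unless the config requests per-subject jitter); each
    session goes through the standard filtering chain (notch + zero-phase
    FIR band-pass) before trimming and segmentation.  Cohort metadata is
    drawn until at least ``n_retained`` subjects survive the screening
    rules.
    """
    from .preprocess import bandpass_fir, notch_filter

    config = config or SimConfig(seed=seed)
    gt = make_ground_truth(config, seed)
    rng = np.random.default_rng(seed)
    retained: list = []
    for attempt in range(50):
        cohort = simulate_cohort_metadata(
            config.n_subjects, seed=int(rng.integers(0, 2**31 - 1)))
        retained, _ = screen_subjects(cohort)
        if n_retained is None or len(retained) >= n_retained:
            break
    if n_retained is not None:
        retained = retained[:n_retained]
    sets = []
    for rec in retained:
        session_seed = int(rng.integers(0, 2**31 - 1))
        session = simulate_session(config, gt, session_seed)
        if notch_hz:
            session = notch_filter(session, notch_hz)
        if band is not None:
            session = bandpass_fir(session, band[0], band[1], fir_order)
        sets.append(build_epochs(
            session, win_s=win_s, overlap_frac=overlap_frac,
            head_s=head_s, tail_s=tail_s, subject_id=rec.subject_id))
    epochs = EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]))
    return epochs, retained
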