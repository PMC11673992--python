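"""Multi-class Common Spatial Patterns (MCCSP).

CSP finds channel projections that maximise the variance of one class while
minimising it for the rest.  The multi-class extension used here whitens by
the composite covariance and extracts per-class filters one-vs-rest:

1. per-trial centering (common average reference, then temporal mean),
2. per-class covariance  R_i = sum_j X_j^T X_j  and composite R = sum_i R_i,
3. eigendecomposition R = U0 L U0^T and whitening W = L^{-1/2} U0^T,
4. whitened class covariances S_i = W R_i W^T (these sum to the identity),
5. eigendecomposition S_i = U_i L_i U_i^T per class,
6. spatial filters SF_i = U_is^T W from the m largest- and m smallest-
   eigenvalue eigenvectors; spatial patterns SP_i = pinv(SF_i),
7. projection Z = X SF^T.

Two filter-bank modes are provided: ``per_class`` returns the literal K
banks of 2m filters; ``composite`` (default) stacks each class's
largest-eigenvalue filters into a single C-row projection so the projected
epochs keep the channel count (a 19-channel, 3-class problem splits
7 + 6 + 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import EpochSet


# ---------------------------------------------------------------------------
# Elementary operations

def center_trial(X: np.ndarray, car: bool = True,
                 temporal: bool = True) -> np.ndarray:
    """Common-average-reference then temporal centering of a T x C trial."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty trial")
    out = X.copy()
    if car:
        out = out - out.mean(axis=1, keepdims=True)
    if temporal:
        out = out - out.mean(axis=0, keepdims=True)
    return out


def class_covariance(trials: list[np.ndarray] | np.ndarray,
                     trace_norm: bool = False) -> np.ndarray:
    """Summed scatter matrix sum_j X_j^T X_j over the trials of one class.

    With ``trace_norm`` each trial's scatter is divided by its trace before
    summing (standard CSP hygiene; off by default to keep the plain sum).
    """
    trials = [np.asarray(t, dtype=float) for t in trials]
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    shape = trials[0].shape
    C = shape[1]
    R = np.zeros((C, C))
    for X in trials:
        if X.shape != shape:
            raise ValueError(f"trial shape {X.shape} != {shape}")
        S = X.T @ X
        if trace_norm:
            tr = np.trace(S)
            if tr > 0:
                S = S / tr
        R += S
    return R


@dataclass
class WhiteningTransform:
    """Whitening map W (r x C) with W R W^T = I_r."""

    W: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    rank: int
    rank_tol: float


def _fix_eigvec_signs(U: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _eigh_desc(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending, stable ties,
    deterministic eigenvector signs."""
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(-vals, kind="stable")
    return vals[order], _fix_eigvec_signs(vecs[:, order])


def whitening_transform(R: np.ndarray,
                        rank_tol: float = 1e-10) -> WhiteningTransform:
    """Whitening from the eigensystem of the composite covariance.

    Eigenvalues below ``rank_tol`` times the largest are treated as zero
    and their components dropped, so W has one row per retained component.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-8 * max(1.0, np.abs(R).max())):
        raise ValueError("R must be symmetric")
    vals, vecs = _eigh_desc(R)
    if vals[0] <= 0:
        raise ValueError("R has no positive eigenvalues")
    keep = vals > rank_tol * vals[0]
    r = int(keep.sum())
    if r == 0:
        raise ValueError("all eigenvalues below tolerance")
    W = (vecs[:, keep] / np.sqrt(vals[keep])).T
    return WhiteningTransform(W=W, eigvals=vals, eigvecs=vecs, rank=r,
                              rank_tol=rank_tol)


def class_spatial_filter(S_i: np.ndarray, W: np.ndarray,
                         m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class filters/patterns from the whitened class covariance.

    Takes the m largest- and m smallest-eigenvalue eigenvectors of S_i
    (eigenvalues sorted descending, ties broken by original index) and maps
    them back through the whitening:  SF = U_sel^T W  (2m x C), SP is the
    pseudoinverse of SF.
    """
    r = S_i.shape[0]
    if 2 * m > r:
        raise ValueError(f"2m = {2 * m} exceeds whitened rank {r}")
    vals, vecs = _eigh_desc(S_i)
    sel = np.concatenate([np.arange(m), np.arange(r - m, r)])
    U_sel = vecs[:, sel]
    SF = U_sel.T @ W
    SP = np.linalg.pinv(SF)
    return SF, SP


@dataclass
class SpatialFilterBank:
    """Fitted MCCSP state: whitening, per-class eigensystems and filters."""

    whitening: WhiteningTransform
    classes: np.ndarray
    S: list[np.ndarray]                 # whitened class covariances
    class_eigvals: list[np.ndarray]
    class_eigvecs: list[np.ndarray]
    m: int
    mode: str
    filters: list[np.ndarray]           # SF_i, 2m x C (per_class)
    patterns: list[np.ndarray]          # SP_i = pinv(SF_i)
    composite_filter: np.ndarray | None = None   # C x C (composite)
    composite_sizes: list[int] = field(default_factory=list)


def composite_row_split(n_channels: int, n_classes: int) -> list[int]:
    """Rows per class in the composite projection: ceil/floor split with
    the remainder given to the earlier classes (19, 3 -> [7, 6, 6])."""
    base = n_channels // n_classes
    rem = n_channels % n_classes
    return [base + (1 if i < rem else 0) for i in range(n_classes)]


def fit_mccsp(epochs: EpochSet | np.ndarray, labels: np.ndarray | None = None,
              m: int = 3, mode: str = "composite", rank_tol: float = 1e-10,
              trace_norm: bool = False, car: bool = True,
              temporal: bool = True) -> SpatialFilterBank:
    """Fit the full MCCSP chain on labelled epochs.

    ``composite`` mode stacks each class's top largest-eigenvalue filters
    into a square C x C projection (channel count preserved); ``per_class``
    keeps the K separate 2m-row banks.
    """
    if isinstance(epochs, EpochSet):
        X, y = epochs.epochs, epochs.labels
    else:
        X, y = np.asarray(epochs), np.asarray(labels)
    if X.ndim != 3:
        raise ValueError("epochs must be n x T x C")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    C = X.shape[2]

    R_list = []
    for cls in classes:
        trials = [center_trial(t, car, temporal) for t in X[y == cls]]
        R_list.append(class_covariance(trials, trace_norm))
    R = np.sum(R_list, axis=0)
    wt = whitening_transform(R, rank_tol)
    if wt.rank < C:
        # CAR removes one dimension at most; deeper deficiency is an error
        if wt.rank < C - 1:
            raise ValueError(
                f"rank-deficient covariance: retained rank {wt.rank} of {C}")

    S_list, evals, evecs, filters, patterns = [], [], [], [], []
    for R_i in R_list:
        S_i = wt.W @ R_i @ wt.W.T
        S_list.append(S_i)
        v, U = _eigh_desc(S_i)
        evals.append(v)
        evecs.append(U)
        SF, SP = class_spatial_filter(S_i, wt.W, min(m, wt.rank // 2))
        filters.append(SF)
        patterns.append(SP)

    bank = SpatialFilterBank(
        whitening=wt, classes=classes, S=S_list, class_eigvals=evals,
        class_eigvecs=evecs, m=m, mode=mode, filters=filters,
        patterns=patterns)

    if mode == "composite":
        sizes = composite_row_split(C, len(classes))
        rows = []
        for i, k in enumerate(sizes):
            k_eff = min(k, wt.rank)
            U_top = evecs[i][:, :k_eff]
            rows.append(U_top.T @ wt.W)
        comp = np.vstack(rows)
        if comp.shape[0] < C:  # rank shortfall: repeat last rows to keep C
            pad = np.tile(comp[-1:], (C - comp.shape[0], 1))
            comp = np.vstack([comp, pad])
        bank.composite_filter = comp
        bank.composite_sizes = sizes
    elif mode != "per_class":
        raise ValueError(f"unknown mode {mode!r}")
    return bank


def project(filter_bank: SpatialFilterBank,
            epochs: EpochSet | np.ndarray,
            which: str | int = "composite") -> np.ndarray:
    """Project epochs onto the CSP space:  Z = X SF^T  per trial.

    ``which`` selects the composite projection or one class's 2m-row bank.
    """
    X = epochs.epochs if isinstance(epochs, EpochSet) else np.asarray(epochs)
    single = X.ndim == 2
    if single:
        X = X[None]
    if which == "composite":
        if filter_bank.composite_filter is None:
            raise ValueError("bank was not fitted in composite mode")
        SF = filter_bank.composite_filter
    else:
        idx = int(np.where(filter_bank.classes == which)[0][0])
        SF = filter_bank.filters[idx]
    if X.shape[2] != SF.shape[1]:
        raise ValueError(
            f"channel mismatch: epochs have {X.shape[2]}, filters expect "
            f"{SF.shape[1]}")
    Z = np.einsum("ntc,fc->ntf", X, SF)
    return Z[0] if single else Z


def projected_variance_table(bank: SpatialFilterBank,
                             epochs: EpochSet) -> np.ndarray:
    """Mean per-component log-variance of composite projections per class
    (numeric stand-in for scalp topographies)."""
    Z = project(bank, epochs)
    out = []
    for cls in bank.classes:
        V = Z[epochs.labels == cls].var(axis=1)
        out.append(np.log(V + 1e-24).mean(axis=0))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Estimator interface

class MCCSP(TransformerMixin, BaseEstimator):
    """Multi-class CSP as a scikit-learn transformer.

    Parameters
    ----------
    m : filters per extreme in ``per_class`` mode.
    mode : 'composite' (C-row projection, channel count preserved) or
        'per_class' (K stacked 2m-row banks, concatenated on transform).
    rank_tol : relative eigenvalue cutoff for the whitening rank.
    trace_norm : per-trial trace normalization of the scatter matrices.
    car, temporal : enable common-average / temporal mean removal.

    Attributes
    ----------
    bank_ : fitted :class:`SpatialFilterBank`.
    filters_ : the projection applied by :meth:`transform`.
    """

    def __init__(self, m: int = 3, mode: str = "composite",
                 rank_tol: float = 1e-10, trace_norm: bool = False,
                 car: bool = True, temporal: bool = True):
        self.m = m
        self.mode = mode
        self.rank_tol = rank_tol
        self.trace_norm = trace_norm
        self.car = car
        self.temporal = temporal

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.bank_ = fit_mccsp(X, y, m=self.m, mode=self.mode,
                               rank_tol=self.rank_tol,
                               trace_norm=self.trace_norm,
                               car=self.car, temporal=self.temporal)
        self.classes_ = self.bank_.classes
        if self.mode == "composite":
            self.filters_ = self.bank_.composite_filter
        else:
            self.filters_ = np.vstack(self.bank_.filters)
        return self

    def transform(self, X):
        check_is_fitted(self, "bank_")
        X = np.asarray(X)
        single = X.ndim == 2
        if single:
            X = X[None]
        Xc = np.stack([center_trial(t, self.car, self.temporal) for t in X])
        Z = np.einsum("ntc,fc->ntf", Xc, self.filters_)
        return Z[0] if single else Z
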