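"""Hand-crafted-feature baseline: 32 features, KW screen, voting ensemble.

The comparison method extracts, per CSP-projected epoch: the 19 per-channel
variances, three autocorrelation summaries (grand-mean autocorrelation,
mean Shannon entropy of the per-channel |acf|, zero-crossings of the
channel-mean acf) and 10 statistics of the pooled multilevel DWT
coefficients — 32 features for a 19-channel epoch.  Features are screened
with a per-feature Kruskal–Wallis test at alpha = 0.05 (no multiplicity
correction), then classified by a bootstrap ensemble of a linear SVM, a
5-NN and a single-hidden-layer MLP with 35 units, combined by majority
vote with ties resolved in favour of the SVM.
"""

from __future__ import annotations

import warnings
import numpy as np
import pywt
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

FEATURE_NAMES_DWT = ["dwt_mean", "dwt_std", "dwt_median", "dwt_max",
                     "dwt_min", "dwt_abs_sum", "dwt_variance",
                     "dwt_skewness", "dwt_kurtosis", "dwt_moment5"]


# ---------------------------------------------------------------------------
# Feature extraction

def _acf(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased normalized autocorrelation at lags 1..n_lags (r(0) = 1)."""
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        return np.zeros(n_lags)
    T = len(x)
    full = np.correlate(x, x, mode="full")[T - 1:]
    return full[1:n_lags + 1] / var


def autocorr_features(Z: np.ndarray, n_lags: int | None = None
                      ) -> tuple[float, float, float]:
    """(mean acf, mean acf entropy, zero-crossings of the mean acf).

    Per channel the biased normalized acf over lags 1..L (L = T//2 by
    default) is computed; the entropy is the Shannon entropy of |acf|
    normalized to a distribution, averaged across channels; zero-crossings
    count sign changes of the across-channel mean acf sequence.
    """
    Z = np.asarray(Z, dtype=float)
    T, C = Z.shape
    if T < 2:
        raise ValueError("need at least 2 samples")
    L = n_lags or T // 2
    acfs = np.stack([_acf(Z[:, c], L) for c in range(C)])
    mean_ac = float(acfs.mean())
    ents = []
    for c in range(C):
        a = np.abs(acfs[c])
        s = a.sum()
        if s == 0:
            ents.append(0.0)
        else:
            p = a / s
            p = p[p > 0]
            ents.append(float(-(p * np.log(p)).sum()))
    entropy = float(np.mean(ents))
    mean_seq = acfs.mean(axis=0)
    sign = np.sign(mean_seq)
    sign = sign[sign != 0]
    zc = float(np.count_nonzero(np.diff(sign)))
    return mean_ac, entropy, zc


def dwt_statistics(Z: np.ndarray, wavelet: str = "db4",
                   level: int = 4) -> np.ndarray:
    """Ten statistics of the pooled DWT coefficients, channel-averaged.

    Per channel a ``level``-deep decomposition is taken; the final
    approximation and all detail coefficients are pooled into one vector on
    which mean, std, median, max, min, absolute sum, variance, skewness,
    kurtosis and the fifth central moment are computed, then averaged
    across channels.  Undefined skew/kurtosis (zero variance) map to 0.
    """
    Z = np.asarray(Z, dtype=float)
    T, C = Z.shape
    max_level = pywt.dwt_max_level(T, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"level {level} too deep for {T} samples (max {max_level})")
    out = np.zeros((C, 10))
    for c in range(C):
        coeffs = np.concatenate(pywt.wavedec(Z[:, c], wavelet, level=level))
        sd = coeffs.std()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(stats.skew(coeffs)) if sd > 0 else 0.0
            kurt = float(stats.kurtosis(coeffs)) if sd > 0 else 0.0
        out[c] = [coeffs.mean(), sd, np.median(coeffs), coeffs.max(),
                  coeffs.min(), np.abs(coeffs).sum(), coeffs.var(),
                  skew, kurt, float(stats.moment(coeffs, 5))]
    return out.mean(axis=0)


def extract_features(Z: np.ndarray, wavelet: str = "db4",
                     level: int = 4) -> np.ndarray:
    """Full feature vector: C variances + 3 acf features + 10 DWT stats."""
    Z = np.asarray(Z, dtype=float)
    variances = Z.var(axis=0)
    mean_ac, ent, zc = autocorr_features(Z)
    dwt = dwt_statistics(Z, wavelet, level)
    return np.concatenate([variances, [mean_ac, ent, zc], dwt])


def feature_names(n_channels: int = 19) -> list[str]:
    return ([f"var_ch{i}" for i in range(n_channels)]
            + ["acf_mean", "acf_entropy", "acf_zero_crossings"]
            + FEATURE_NAMES_DWT)


def extract_feature_matrix(epochs: np.ndarray, wavelet: str = "db4",
                           level: int = 4) -> np.ndarray:
    return np.stack([extract_features(e, wavelet, level) for e in epochs])


# ---------------------------------------------------------------------------
# Kruskal–Wallis screening

def kruskal_wallis_screen(features: np.ndarray, labels: np.ndarray,
                          alpha: float = 0.05
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature Kruskal–Wallis H test.

    Returns (retained indices, H statistics, p-values).  H uses the
    standard tie correction with a chi-square reference on K-1 degrees of
    freedom; features constant across all samples get p = 1.  No
    multiple-testing correction is applied.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 groups")
    groups_idx = [np.where(labels == c)[0] for c in classes]
    if any(len(g) < 2 for g in groups_idx):
        raise ValueError("need at least 2 samples per group")
    H = np.zeros(features.shape[1])
    p = np.ones(features.shape[1])
    for j in range(features.shape[1]):
        col = features[:, j]
        if np.all(col == col[0]):
            H[j], p[j] = 0.0, 1.0
            continue
        samples = [col[g] for g in groups_idx]
        H[j], p[j] = stats.kruskal(*samples)
    retained = np.where(p < alpha)[0]
    return retained, H, p


class KruskalWallisSelector(TransformerMixin, BaseEstimator):
    """Feature selector keeping features with KW p-value below alpha."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        self.retained_, self.H_, self.pvalues_ = kruskal_wallis_screen(
            X, y, self.alpha)
        if len(self.retained_) == 0:
            # keep the single best feature rather than emit an empty matrix
            self.retained_ = np.array([int(np.argmin(self.pvalues_))])
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        return np.asarray(X)[:, self.retained_]


# ---------------------------------------------------------------------------
# Bootstrap voting ensemble

class BaselineVotingEnsemble(ClassifierMixin, BaseEstimator):
    """Majority vote of linear SVM, 5-NN and a 35-unit MLP.

    Each learner is fitted on an independent bootstrap resample (size of
    the training set, with replacement; resamples missing a class are
    redrawn).  Three-way ties go to the SVM's label.

    ``standardize`` inserts a per-learner feature scaler.  The reference
    procedure feeds the raw feature vectors to the classifiers, so it is
    off by default; on well-conditioned planted data the scaled variant
    can saturate the task (the per-channel variances alone are then
    linearly separable).
    """

    def __init__(self, n_neighbors: int = 5, mlp_hidden: int = 35,
                 standardize: bool = False, random_state: int = 0,
                 max_redraws: int = 100):
        self.n_neighbors = n_neighbors
        self.mlp_hidden = mlp_hidden
        self.standardize = standardize
        self.random_state = random_state
        self.max_redraws = max_redraws

    def _bootstrap(self, rng, y):
        n = len(y)
        n_classes = len(np.unique(y))
        for _ in range(self.max_redraws):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == n_classes:
                return idx
        raise RuntimeError("could not draw a bootstrap sample with all "
                           "classes present")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        learners = [
            SVC(kernel="linear", random_state=self.random_state),
            KNeighborsClassifier(n_neighbors=self.n_neighbors),
            MLPClassifier(hidden_layer_sizes=(self.mlp_hidden,),
                          max_iter=1000, random_state=self.random_state),
        ]
        if self.standardize:
            learners = [make_pipeline(StandardScaler(), l)
                        for l in learners]
        self.learners_ = learners
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for learner in self.learners_:
                idx = self._bootstrap(rng, y)
                learner.fit(X[idx], y[idx])
        return self

    def predict(self, X):
        check_is_fitted(self, "learners_")
        X = np.asarray(X, dtype=float)
        votes = np.stack([l.predict(X) for l in self.learners_])
        svm_votes = votes[0]
        out = np.empty(len(X), dtype=self.classes_.dtype)
        for i in range(len(X)):
            vals, counts = np.unique(votes[:, i], return_counts=True)
            best = counts.max()
            winners = vals[counts == best]
            if len(winners) == 1:
                out[i] = winners[0]
            else:
                out[i] = svm_votes[i]
        return out


def fit_baseline(features: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.05, seed: int = 0
                 ) -> tuple[KruskalWallisSelector, BaselineVotingEnsemble]:
    """Screen features then fit the voting ensemble on the retained ones."""
    sel = KruskalWallisSelector(alpha=alpha).fit(features, labels)
    model = BaselineVotingEnsemble(random_state=seed).fit(
        sel.transform(features), labels)
    return sel, model


def predict_baseline(selector: KruskalWallisSelector,
                     model: BaselineVotingEnsemble,
                     features: np.ndarray) -> np.ndarray:
    return model.predict(selector.transform(features))
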