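"""CSP-feature classification: LDA (default) or RBF-SVM, 10-fold CV,
and sliding-window evaluation.

Cross-validation is stratified and leak-free: the band-pass is applied and
the CSP filters are fitted inside each training fold, never on test epochs.
Chance level is exactly 0.5 (balanced two-class left/right design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import EpochSet
from .csp import CSPModel, csp_features, fit_csp
from .preprocess import FilterSpec, filter_array

__all__ = [
    "PipelineSpec",
    "LDAModel",
    "CVReport",
    "SlidingWindowReport",
    "fit_lda",
    "fit_svm_rbf",
    "crossval",
    "sliding_window_eval",
]


@dataclass(frozen=True)
class PipelineSpec:
    """One classification pipeline: band -> window -> CSP(m) -> classifier."""

    band: tuple[float, float] | None = (4.0, 20.0)
    filter_order: int = 4
    window_ms: tuple[float, float] = (0.0, 1000.0)
    m: int = 3
    shrinkage: float | str = "auto"
    classifier: str = "lda"  # or "svm"
    svm_C: float = 0.4


@dataclass
class LDAModel:
    """Two-class linear discriminant: w = pooledSigma^-1 (mu1 - mu0)."""

    classes: np.ndarray
    means: np.ndarray  # (2, d)
    covariance: np.ndarray  # pooled within-class
    priors: np.ndarray
    weights: np.ndarray
    bias: float
    _clf: LinearDiscriminantAnalysis = field(repr=False, default=None)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes[1], self.classes[0])

    def score(self, X: np.ndarray, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class CVReport:
    fold_accuracies: np.ndarray
    mean: float
    sd: float
    k: int
    seed: int
    n_per_class: dict
    classes: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"CV accuracy {self.mean:.4f} +/- {self.sd:.4f} over {self.k} folds"


@dataclass
class SlidingWindowReport:
    window_starts_ms: np.ndarray
    accuracies: np.ndarray
    window_ms: float
    step_ms: float


def fit_lda(X: np.ndarray, y) -> LDAModel:
    """Fit a two-class LDA with pooled within-class covariance.

    Falls back to Ledoit-Wolf shrinkage of the pooled covariance (with a
    warning) when it is numerically singular.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"LDA here is two-class; got classes {classes}")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")

    pooled = sum(np.cov(X[y == c], rowvar=False, bias=False) * ((y == c).sum() - 1)
                 for c in classes) / (len(X) - 2)
    pooled = np.atleast_2d(pooled)
    singular = np.linalg.cond(pooled) > 1e12
    shrink = None
    if singular:
        warnings.warn("singular pooled covariance; using shrinkage LDA", stacklevel=2)
        shrink = "auto"
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrink)
    clf.fit(X, y)
    return LDAModel(
        classes=classes,
        means=np.stack([X[y == c].mean(axis=0) for c in classes]),
        covariance=pooled,
        priors=clf.priors_,
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        _clf=clf,
    )


def fit_svm_rbf(X: np.ndarray, y, C: float = 0.4, gamma="scale") -> SVC:
    """RBF-kernel soft-margin SVM at the study's C; gamma = 1/(d * var(X))."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM needs two classes")
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(np.asarray(X, float), y)
    return clf


def _prepare(data: np.ndarray, epochs: EpochSet, spec: PipelineSpec) -> np.ndarray:
    """Band-filter then crop a (k, ch, t) block to the spec's window."""
    if spec.band is not None:
        fspec = FilterSpec(spec.band[0], spec.band[1], order=spec.filter_order)
        data = filter_array(data, fspec, epochs.fs, axis=2)
    t = epochs.times
    lo = int(np.searchsorted(t, spec.window_ms[0] - 1e-9))
    hi = int(np.searchsorted(t, spec.window_ms[1] + 1e-9))
    return data[:, :, lo:hi]


def _fit_fold(
    train_data: np.ndarray,
    train_y: np.ndarray,
    epochs: EpochSet,
    spec: PipelineSpec,
    classes,
) -> tuple[CSPModel, object]:
    """Fit band filter -> CSP -> classifier on training epochs only."""
    Xtr = _prepare(train_data, epochs, spec)
    model = fit_csp(Xtr[train_y == classes[0]], Xtr[train_y == classes[1]],
                    m=spec.m, shrinkage=spec.shrinkage)
    feats = csp_features(model, Xtr)
    if spec.classifier == "lda":
        clf = fit_lda(feats, train_y)
    elif spec.classifier == "svm":
        clf = fit_svm_rbf(feats, train_y, C=spec.svm_C)
    else:
        raise ValueError(f"unknown classifier {spec.classifier!r}")
    return model, clf


def crossval(
    epochs: EpochSet,
    spec: PipelineSpec = PipelineSpec(),
    k: int = 10,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> CVReport:
    """Stratified k-fold CV of the band->CSP->classifier pipeline.

    ``labels`` overrides the epoch labels (e.g. for permutation nulls).
    """
    y = np.asarray(labels if labels is not None else epochs.labels)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < k:
        raise ValueError(f"k={k} exceeds smallest class size {min(counts.values())}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        model, clf = _fit_fold(epochs.data[tr], y[tr], epochs, spec, classes)
        Xte = _prepare(epochs.data[te], epochs, spec)
        feats = csp_features(model, Xte)
        accs.append(clf.score(feats, y[te]))
    accs = np.asarray(accs)
    return CVReport(
        fold_accuracies=accs,
        mean=float(accs.mean()),
        sd=float(accs.std(ddof=1)) if k > 1 else 0.0,
        k=k,
        seed=seed,
        n_per_class=counts,
        classes=classes,
    )


def sliding_window_eval(
    epochs: EpochSet,
    spec: PipelineSpec = PipelineSpec(),
    win: float = 500.0,
    step: float = 100.0,
    k: int = 10,
    seed: int = 0,
) -> SlidingWindowReport:
    """CV accuracy per sliding window (length ``win`` ms, step ``step`` ms).

    Windows tile the spec's window_ms span: 0..1000 ms at 500/100 gives six
    windows starting 0, 100, ..., 500 ms.
    """
    lo, hi = spec.window_ms
    if win > hi - lo:
        raise ValueError(f"window {win} ms exceeds evaluation span {hi - lo} ms")
    starts = np.arange(lo, hi - win + 1e-9, step)
    accs = []
    for s in starts:
        wspec = replace(spec, window_ms=(float(s), float(s + win)))
        accs.append(crossval(epochs, wspec, k=k, seed=seed).mean)
    return SlidingWindowReport(
        window_starts_ms=np.asarray(starts, float),
        accuracies=np.asarray(accs),
        window_ms=win,
        step_ms=step,
    )
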