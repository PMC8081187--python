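"""Common Spatial Patterns by simultaneous diagonalization of class covariances.

Given single-trial channel data E (N channels x T samples) the spatial
filter maps Z = W E.  W solves the generalized eigenproblem

    Sigma_A w = lambda (Sigma_A + Sigma_B) w

so each filter's eigenvalue lambda in [0, 1] is the share of class-A variance
in the composite; filters with extreme lambda maximise the variance of one
class while minimising the other's.  The classifier input is the
log-variance feature of each selected row Zp:

    x_p = log( var(Zp) / sum_i var(Zi) ),   i over the 2m selected rows,

which is scale-invariant and bounded above by 0.  Per-trial covariances are
trace-normalized before averaging, and shrunk toward a scaled identity
(Ledoit-Wolf-style) to keep 30-channel estimates from ~1,000-sample epochs
well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage

from .containers import EpochSet

__all__ = ["CSPModel", "class_covariance", "fit_csp", "fit_csp_from_cov", "csp_features"]


@dataclass
class CSPModel:
    """Fitted CSP filters.

    W : (N, N) projection matrix, rows are spatial filters, ordered by
        eigenvalue descending.
    eigenvalues : per-filter class-A variance ratio, descending in [0, 1].
    selected_idx : indices of the 2m retained filters (m from each end).
    patterns : (N, N) matrix whose columns are the scalp patterns (W^-1).
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    selected_idx: np.ndarray
    patterns: np.ndarray
    m: int
    n_channels: int
    shrinkage: float = 0.0

    @property
    def W_selected(self) -> np.ndarray:
        return self.W[self.selected_idx]


def _epochs_array(epochs) -> np.ndarray:
    if isinstance(epochs, EpochSet):
        return epochs.data
    x = np.asarray(epochs, float)
    if x.ndim == 2:
        x = x[None]
    return x


def class_covariance(epochs, shrinkage: float | str = 0.0) -> np.ndarray:
    """Average trace-normalized per-epoch channel covariance.

    Each epoch E contributes E Eᵀ / trace(E Eᵀ); the average over epochs has
    unit trace.  ``shrinkage`` in [0, 1] blends toward (trace/N)·I; "auto"
    estimates the intensity by the Ledoit-Wolf formula on the pooled samples.
    """
    X = _epochs_array(epochs)
    if X.shape[0] < 1:
        raise ValueError("need at least one epoch")
    n_ch = X.shape[1]
    covs = np.einsum("kct,kdt->kcd", X, X)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("epoch with zero total variance")
    cov = (covs / traces[:, None, None]).mean(axis=0)
    cov = 0.5 * (cov + cov.T)

    if shrinkage == "auto":
        pooled = np.concatenate([e.T for e in X], axis=0)
        pooled = pooled - pooled.mean(axis=0)
        shrinkage = float(ledoit_wolf_shrinkage(pooled))
    gamma = float(shrinkage)
    if not 0 <= gamma <= 1:
        raise ValueError(f"shrinkage must be in [0, 1], got {gamma}")
    if gamma > 0:
        cov = (1 - gamma) * cov + gamma * (np.trace(cov) / n_ch) * np.eye(n_ch)
    return cov


def _fix_signs(W: np.ndarray, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each filter so its largest-|.| pattern coefficient is positive.

    Ties broken by lowest channel index (argmax picks the first maximum).
    """
    W = W.copy()
    patterns = patterns.copy()
    for j in range(W.shape[0]):
        col = patterns[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            W[j] *= -1
            patterns[:, j] *= -1
    return W, patterns


def fit_csp_from_cov(cov_a: np.ndarray, cov_b: np.ndarray, m: int = 3) -> CSPModel:
    """Fit CSP directly from two class covariance matrices."""
    cov_a = np.asarray(cov_a, float)
    cov_b = np.asarray(cov_b, float)
    n = cov_a.shape[0]
    if cov_a.shape != (n, n) or cov_b.shape != (n, n):
        raise ValueError("covariances must be square and same shape")
    if m < 1 or 2 * m > n:
        raise ValueError(f"need 1 <= m and 2m <= {n} channels, got m={m}")
    for name, c in (("A", cov_a), ("B", cov_b)):
        ev = linalg.eigvalsh(0.5 * (c + c.T))
        if ev.min() < -1e-10 * max(1.0, ev.max()):
            raise ValueError(f"class-{name} covariance is not positive semi-definite")

    composite = cov_a + cov_b
    # generalized symmetric eigenproblem; scipy normalizes w^T composite w = 1,
    # hence W (Sigma_A + Sigma_B) W^T = I
    eigvals, eigvecs = linalg.eigh(cov_a, composite)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, 1.0)
    W = eigvecs[:, order].T
    patterns = linalg.inv(W)
    W, patterns = _fix_signs(W, patterns)
    selected = np.concatenate([np.arange(m), np.arange(n - m, n)])
    return CSPModel(
        W=W,
        eigenvalues=eigvals,
        selected_idx=selected,
        patterns=patterns,
        m=m,
        n_channels=n,
    )


def fit_csp(
    epochs_a,
    epochs_b,
    m: int = 3,
    shrinkage: float | str = "auto",
) -> CSPModel:
    """Fit CSP from two sets of single-trial epochs (class A vs class B)."""
    Xa, Xb = _epochs_array(epochs_a), _epochs_array(epochs_b)
    if Xa.shape[0] < 2 or Xb.shape[0] < 2:
        raise ValueError("need at least two epochs per class")
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("classes disagree on channel count")
    cov_a = class_covariance(Xa, shrinkage=shrinkage)
    cov_b = class_covariance(Xb, shrinkage=shrinkage)
    model = fit_csp_from_cov(cov_a, cov_b, m=m)
    if shrinkage == "auto":
        model.shrinkage = float("nan")  # per-class auto intensities
    else:
        model.shrinkage = float(shrinkage)
    return model


def csp_features(model: CSPModel, epochs) -> np.ndarray:
    """Log-variance features of the selected filters.

    For each epoch: project Z = W_sel E, take per-row variance over samples,
    return log(var_p / sum var).  Shape (n_epochs, 2m) for 3-D input, (2m,)
    for a single epoch.
    """
    X = _epochs_array(epochs)
    single = np.asarray(epochs).ndim == 2 if not isinstance(epochs, EpochSet) else False
    if X.shape[1] != model.n_channels:
        raise ValueError(
            f"epoch has {X.shape[1]} channels, model expects {model.n_channels}"
        )
    Z = np.einsum("fc,kct->kft", model.W_selected, X)
    var = Z.var(axis=2)
    total = var.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("epoch with zero projected variance")
    feats = np.log(var / total)
    return feats[0] if single else feats
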