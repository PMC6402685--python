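"""Template matching by canonical correlation analysis.

Per-target templates are the mean of the training epochs.  A test trial
is identified by averaging its epochs, computing the canonical
correlations between the averaged trial and each template (channels as
variables, samples as observations), taking the mean of each target's
canonical-correlation vector as its feature, and picking the argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preproc import EpochArray

__all__ = ["TemplateSet", "CCAResult", "build_templates", "canonical_correlations", "identify_cca"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemplateSet:
    """Per-target mean training epochs (each channels x samples)."""

    templates: np.ndarray  # targets x channels x samples
    labels: tuple[str, ...]
    fs_hz: float

    @property
    def n_targets(self) -> int:
        return self.templates.shape[0]


@dataclass(frozen=True)
class CCAResult:
    """Canonical correlations (descending, each in [0,1]) and weights."""

    canonical_correlations: np.ndarray
    weights_x: np.ndarray  # channels x components
    weights_y: np.ndarray

    @property
    def feature(self) -> float:
        """Mean of the canonical-correlation vector — the decoder feature."""
        return float(self.canonical_correlations.mean())


def build_templates(train: dict[str, EpochArray] | dict[str, np.ndarray], fs_hz: float | None = None) -> TemplateSet:
    """Average each target's training epochs into its template.

    ``train`` maps target label to an EpochArray (or raw epochs x
    channels x samples array; then ``fs_hz`` must be given).
    """
    labels = tuple(train.keys())
    if not labels:
        raise ValueError("no targets provided")
    temps = []
    for label in labels:
        ep = train[label]
        if isinstance(ep, EpochArray):
            data, fs = ep.data, ep.fs_hz
        else:
            data = np.asarray(ep, dtype=float)
            fs = fs_hz
            if fs is None:
                raise ValueError("fs_hz required when passing raw arrays")
        if data.ndim != 3 or data.shape[0] < 1:
            raise ValueError(f"target {label!r}: need at least one epoch (epochs x ch x samples)")
        temps.append(data.mean(axis=0))
    templates = np.stack(temps)
    return TemplateSet(templates=templates, labels=labels, fs_hz=float(fs))


def canonical_correlations(X: np.ndarray, Y: np.ndarray, reg: float = 1e-8) -> CCAResult:
    """All canonical correlations between the row spaces of X and Y (m x n).

    Rows (channels) are the variables, columns the samples; both are
    centered internally.  The auto-covariance blocks are regularized by
    ``reg`` times their average diagonal before whitening; the canonical
    correlations are the singular values of the whitened cross-covariance,
    returned descending and clipped to [0, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"X and Y must share a shape, got {X.shape} and {Y.shape}")
    m, n = X.shape
    if n <= m:
        raise ValueError(f"need more samples than channels, got m={m}, n={n}")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if not Xc.any() or not Yc.any():
        raise ValueError("zero-variance input: canonical correlation is undefined")
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    Cxx = Cxx + reg * (np.trace(Cxx) / m) * np.eye(m)
    Cyy = Cyy + reg * (np.trace(Cyy) / m) * np.eye(m)
    try:
        Lx = scipy.linalg.cholesky(Cxx, lower=True)
        Ly = scipy.linalg.cholesky(Cyy, lower=True)
    except scipy.linalg.LinAlgError as exc:
        rank = np.linalg.matrix_rank(Cxx), np.linalg.matrix_rank(Cyy)
        raise ValueError(
            f"rank-deficient covariance after regularization (effective ranks {rank})"
        ) from exc
    K = scipy.linalg.solve_triangular(Lx, Cxy, lower=True)
    K = scipy.linalg.solve_triangular(Ly, K.T, lower=True).T
    U, s, Vt = np.linalg.svd(K)
    corrs = np.clip(s, 0.0, 1.0)
    Wx = scipy.linalg.solve_triangular(Lx, U, lower=True, trans="T")
    Wy = scipy.linalg.solve_triangular(Ly, Vt.T, lower=True, trans="T")
    return CCAResult(canonical_correlations=corrs, weights_x=Wx, weights_y=Wy)


def identify_cca(
    test_trial: EpochArray,
    templates: TemplateSet,
    n_epochs_used: int | None = None,
    reg: float = 1e-8,
    feature: str = "mean",
) -> tuple[int, np.ndarray]:
    """Identify the attended target of one test trial.

    Averages the first ``n_epochs_used`` epochs, computes the canonical
    correlations against every template and reduces each correlation
    vector to a scalar feature (``'mean'`` of all coefficients, or
    ``'max'`` for the leading one only).  Returns the 1-based target
    index (tie -> lowest index, logged) and the feature vector.
    """
    s = test_trial.mean_epoch(n_epochs_used)
    if s.shape != templates.templates.shape[1:]:
        raise ValueError(
            f"test trial shape {s.shape} does not match templates {templates.templates.shape[1:]}"
        )
    if feature not in ("mean", "max"):
        raise ValueError(f"unknown feature reduction {feature!r}")
    rho = np.empty(templates.n_targets)
    for i in range(templates.n_targets):
        res = canonical_correlations(s, templates.templates[i], reg=reg)
        rho[i] = res.feature if feature == "mean" else float(res.canonical_correlations[0])
    best = int(np.argmax(rho))
    if np.sum(rho == rho[best]) > 1:
        logger.warning("tie between targets %s; choosing the lowest index", np.flatnonzero(rho == rho[best]) + 1)
    return best + 1, rho
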