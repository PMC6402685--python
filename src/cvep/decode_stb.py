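"""Spatiotemporal LCMV beamforming for target identification.

Each target's activation pattern a_i is its mean training epoch with
channels concatenated into one vector of length m*n.  The beamformer
w_i = Sigma^-1 a_i / (a_i^T Sigma^-1 a_i) passes that pattern with unit
gain (a_i^T w_i = 1) while minimizing output variance under the
covariance Sigma of all concatenated training epochs.  A test trial is
scored by y_i = s . w_i for its averaged, concatenated epoch s; the
attended target is the argmax.

With m*n in the hundreds and fewer training epochs than that, the raw
sample covariance is singular; Sigma is therefore shrunk toward its
diagonal by a configurable weight before inversion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preproc import EpochArray

__all__ = ["BeamformerSet", "build_beamformers", "identify_stb"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeamformerSet:
    """Per-target activation patterns and LCMV weights (each length m*n)."""

    patterns: np.ndarray  # targets x (m*n)
    beamformers: np.ndarray  # targets x (m*n)
    covariance: np.ndarray  # (m*n) x (m*n), shrunk
    shrinkage: float
    labels: tuple[str, ...]
    n_channels: int
    n_samples: int
    fs_hz: float

    @property
    def n_targets(self) -> int:
        return self.patterns.shape[0]


def _concat_epochs(data: np.ndarray) -> np.ndarray:
    """epochs x channels x samples -> epochs x (channels*samples)."""
    k, m, n = data.shape
    return data.reshape(k, m * n)


def build_beamformers(
    train: dict[str, EpochArray] | dict[str, np.ndarray],
    shrinkage: float = 0.05,
    fs_hz: float | None = None,
) -> BeamformerSet:
    """Construct per-target LCMV beamformers from training epochs.

    Sigma is the sample covariance of all targets' concatenated training
    epochs jointly, shrunk toward its diagonal:
    ``Sigma = (1 - shrinkage) * S + shrinkage * diag(S)``.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    labels = tuple(train.keys())
    if not labels:
        raise ValueError("no targets provided")
    blocks, patterns = [], []
    fs = fs_hz
    shape = None
    for label in labels:
        ep = train[label]
        if isinstance(ep, EpochArray):
            data, fs = ep.data, ep.fs_hz
        else:
            data = np.asarray(ep, dtype=float)
            if fs is None:
                raise ValueError("fs_hz required when passing raw arrays")
        if shape is None:
            shape = data.shape[1:]
        elif data.shape[1:] != shape:
            raise ValueError("all targets must share channel/sample dimensions")
        blocks.append(_concat_epochs(data))
        patterns.append(data.mean(axis=0).ravel())
    X = np.concatenate(blocks, axis=0)
    h, mn = X.shape
    if h < 2:
        raise ValueError("need at least two training epochs in total")
    if h <= mn:
        warnings.warn(
            f"only {h} training epochs for a {mn}-dimensional covariance; "
            "the sample covariance is ill-conditioned and relies on shrinkage",
            stacklevel=2,
        )
    S = np.cov(X, rowvar=False)
    sigma = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    A = np.stack(patterns)
    try:
        cho = scipy.linalg.cho_factor(sigma)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance matrix is singular; increase shrinkage above 0"
        ) from exc
    sol = scipy.linalg.cho_solve(cho, A.T)  # Sigma^-1 a_i, columns
    denom = np.einsum("ij,ji->i", A, sol)
    if np.any(denom <= 0):
        raise ValueError("non-positive a^T Sigma^-1 a; covariance not positive definite")
    W = (sol / denom).T
    m, n = shape
    return BeamformerSet(
        patterns=A,
        beamformers=W,
        covariance=sigma,
        shrinkage=shrinkage,
        labels=labels,
        n_channels=m,
        n_samples=n,
        fs_hz=float(fs),
    )


def identify_stb(
    test_trial: EpochArray,
    bf: BeamformerSet,
    n_epochs_used: int | None = None,
) -> tuple[int, np.ndarray]:
    """Identify a test trial's target by maximum beamformer output.

    Averages the first ``n_epochs_used`` epochs, concatenates channels
    into s (length m*n) and returns the 1-based argmax of y_i = s . w_i
    (tie -> lowest index, logged) together with the score vector y.
    """
    s = test_trial.mean_epoch(n_epochs_used)
    if s.shape != (bf.n_channels, bf.n_samples):
        raise ValueError(
            f"test trial shape {s.shape} does not match beamformers "
            f"({bf.n_channels}, {bf.n_samples})"
        )
    y = bf.beamformers @ s.ravel()
    best = int(np.argmax(y))
    if np.sum(y == y[best]) > 1:
        logger.warning(
            "tie between targets %s; choosing the lowest index",
            np.flatnonzero(y == y[best]) + 1,
        )
    return best + 1, y
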