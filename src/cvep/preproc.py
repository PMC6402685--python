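"""Filtering, detrending and trigger-aligned epoch segmentation.

Order of operations mirrors the recording protocol: trials are cut at
the triggers first, then each trial segment is band-pass filtered
(zero-phase Butterworth, 2-40 Hz, order 8) and linearly detrended, and
finally reshaped into its 18 consecutive code epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .synthdata import EEGRecording

__all__ = [
    "EpochArray",
    "TrialSegment",
    "epoch_samples",
    "bandpass",
    "detrend",
    "extract_trials",
    "extract_epochs",
    "preprocess_study",
]


@dataclass(frozen=True)
class TrialSegment:
    """One trial's continuous multichannel data (channels x samples)."""

    data: np.ndarray
    fs_hz: float
    target_label: str = ""
    onset_sample: int = 0


@dataclass(frozen=True)
class EpochArray:
    """Stack of per-epoch responses: epochs x channels x samples."""

    data: np.ndarray
    fs_hz: float
    target_label: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("EpochArray data must be epochs x channels x samples")
        if not np.isfinite(data).all():
            raise ValueError("EpochArray data must be finite")
        object.__setattr__(self, "data", data)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def mean_epoch(self, n_epochs_used: int | None = None) -> np.ndarray:
        """Average of the first ``n_epochs_used`` epochs (channels x samples)."""
        r = self.n_epochs if n_epochs_used is None else int(n_epochs_used)
        if not 1 <= r <= self.n_epochs:
            raise ValueError(f"n_epochs_used must lie in 1..{self.n_epochs}, got {r}")
        return self.data[:r].mean(axis=0)


def epoch_samples(fs_hz: float, code_length_bits: int = 31, rate_hz: float = 90.0) -> int:
    """Samples per code epoch: round(fs * L / rate)."""
    return round(fs_hz * code_length_bits / rate_hz)


def _apply(rec, func):
    """Apply a per-channel transform to an EEGRecording or TrialSegment."""
    return replace(rec, data=func(np.asarray(rec.data, dtype=float)))


def bandpass(rec, low: float = 2.0, high: float = 40.0, order: int = 8):
    """Zero-phase Butterworth band-pass; triggers untouched.

    ``order`` is the order of the band-pass transfer function (the design
    uses ``order/2`` pole pairs per edge); forward-backward application
    doubles the attenuation and cancels the phase.
    """
    if order % 2:
        raise ValueError("band-pass order must be even")
    nyq = rec.fs_hz / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq} Hz), got {low}, {high}"
        )
    sos = scipy.signal.butter(order // 2, [low, high], btype="bandpass", fs=rec.fs_hz, output="sos")
    return _apply(rec, lambda d: scipy.signal.sosfiltfilt(sos, d, axis=-1))


def detrend(rec):
    """Remove each channel's best-fit line (baseline correction)."""
    return _apply(rec, lambda d: scipy.signal.detrend(d, axis=-1, type="linear"))


def extract_trials(
    rec: EEGRecording,
    epochs_per_trial: int = 18,
    code_length_bits: int = 31,
    rate_hz: float = 90.0,
) -> list[TrialSegment]:
    """Cut one segment of ``epochs_per_trial * n`` samples at each trigger.

    ``n = round(fs * L / rate)`` is the fixed epoch length.  Raises if a
    trigger sits too close to the end of the data or if consecutive trial
    windows would overlap.  Zero triggers yield an empty list.
    """
    n = epoch_samples(rec.fs_hz, code_length_bits, rate_hz)
    t_trial = epochs_per_trial * n
    segments: list[TrialSegment] = []
    trig = rec.trigger_samples
    for i, onset in enumerate(trig):
        if onset + t_trial > rec.n_samples:
            raise ValueError(
                f"trigger {i} at sample {onset} leaves fewer than {t_trial} samples"
            )
        if i + 1 < trig.size and onset + t_trial > trig[i + 1]:
            raise ValueError(
                f"trial window at trigger {i} (sample {onset}) overlaps trigger {i + 1}"
            )
        label = rec.annotations[i] if rec.annotations else ""
        segments.append(
            TrialSegment(
                data=rec.data[:, onset : onset + t_trial].copy(),
                fs_hz=rec.fs_hz,
                target_label=label,
                onset_sample=int(onset),
            )
        )
    return segments


def extract_epochs(
    segment: TrialSegment,
    epochs_per_trial: int = 18,
    code_length_bits: int = 31,
    rate_hz: float = 90.0,
) -> EpochArray:
    """Reshape a trial into consecutive non-overlapping code epochs.

    Epoch boundaries are cumulative sample counts from the trial onset
    (epoch e spans samples [e*n, (e+1)*n)), so concatenating the epochs
    reconstructs the segment bit-exactly.
    """
    n = epoch_samples(segment.fs_hz, code_length_bits, rate_hz)
    m, total = segment.data.shape
    needed = epochs_per_trial * n
    if abs(total - needed) > 1:
        raise ValueError(
            f"segment has {total} samples; expected {epochs_per_trial} epochs of {n}"
        )
    data = segment.data
    if total == needed - 1:  # one sample short from rounding: repeat the last sample
        data = np.concatenate([data, data[:, -1:]], axis=1)
    epochs = data[:, :needed].reshape(m, epochs_per_trial, n).transpose(1, 0, 2)
    return EpochArray(data=epochs, fs_hz=segment.fs_hz, target_label=segment.target_label)


def preprocess_study(
    recordings: dict[str, EEGRecording],
    low: float = 2.0,
    high: float = 40.0,
    order: int = 8,
    epochs_per_trial: int = 18,
    code_length_bits: int = 31,
    rate_hz: float = 90.0,
    filter_data: bool = True,
) -> dict[str, list[EpochArray]]:
    """Full preprocessing: cut trials, filter, detrend, epoch — per target.

    Returns ``{target_label: [EpochArray per trial]}`` preserving trial
    order.  ``filter_data=False`` skips filtering/detrending (useful for
    noiseless oracle checks where edge effects matter).
    """
    out: dict[str, list[EpochArray]] = {}
    for label, rec in recordings.items():
        trials = []
        for seg in extract_trials(rec, epochs_per_trial, code_length_bits, rate_hz):
            if filter_data:
                seg = detrend(bandpass(seg, low, high, order))
            trials.append(extract_epochs(seg, epochs_per_trial, code_length_bits, rate_hz))
        out[label] = trials
    return out
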