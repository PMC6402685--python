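"""Synthetic EEG recordings and fatigue-score tables.

The simulator emulates the statistical structure a code-modulated VEP
analysis relies on: each attended target evokes the convolution of its
(lagged) code waveform with a subject-specific evoked-impulse kernel,
mixed into 4 occipital channels (Oz, O1, O2, Pz) at per-channel gains and
buried in a pink + white noise background at a prescribed SNR.  Because
convolution is shift-equivariant, the imposed 8-bit lags between targets
are preserved in the evoked responses, which is exactly the property the
decoders exploit.

A companion generator produces per-subject visual-analogue fatigue
scores (0-10) for the two code families with a shared within-subject
latent, for exercising the paired statistical battery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .codes import BinaryCode, StimulusSet

__all__ = [
    "VEPKernel",
    "SimulationConfig",
    "EEGRecording",
    "VASTable",
    "make_vep_kernel",
    "simulate_recording",
    "simulate_study",
    "simulate_vas",
]

CHANNEL_LABELS = ("Oz", "O1", "O2", "Pz")


@dataclass(frozen=True)
class VEPKernel:
    """Evoked impulse response: what one light flash adds to the EEG."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or not np.isfinite(samples).all():
            raise ValueError("kernel samples must be a finite 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated session.

    Defaults mirror the recording protocol: 4 occipital channels,
    10 trials of 18 code epochs (6.2 s of stimulation for a 31-bit code
    at 90 Hz) separated by 2 s breaks.  Simulation runs at 600 Hz by
    default rather than the 4800 Hz acquisition rate; the decoders
    operate on epoch shapes, not absolute sampling rate.  ``snr_db`` is
    the evoked-signal to background-noise power ratio over the
    stimulation samples; ``math.inf`` disables noise and ``-math.inf``
    disables the signal (noise-only control).
    """

    fs_hz: float = 600.0
    n_channels: int = 4
    channel_labels: tuple[str, ...] = CHANNEL_LABELS
    mixing_weights: tuple[float, ...] = (1.0, 0.85, 0.8, 0.55)
    white_sd: float = 1.0
    pink_fraction: float = 0.5
    snr_db: float = -5.0
    n_trials: int = 10
    epochs_per_trial: int = 18
    break_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels must match n_channels")
        if len(self.mixing_weights) != self.n_channels:
            raise ValueError("mixing_weights must match n_channels")
        if any(w <= 0 for w in self.mixing_weights):
            raise ValueError("mixing_weights must be positive")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must lie in [0, 1]")

    def validate_rate(self, rate_hz: float) -> None:
        ratio = self.fs_hz / rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            warnings.warn(
                f"fs_hz={self.fs_hz} is not an integer multiple of the code rate "
                f"{rate_hz} Hz; epoch boundaries will drift by fractional samples",
                stacklevel=3,
            )


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel recording with trial-onset triggers.

    ``data`` is channels x samples (arbitrary units), ``trigger_samples``
    the strictly increasing trial onsets, ``annotations`` the per-trial
    target label.
    """

    data: np.ndarray
    fs_hz: float
    trigger_samples: np.ndarray
    channel_labels: tuple[str, ...]
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        trig = np.asarray(self.trigger_samples, dtype=np.int64)
        if data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{data.shape[0]} data rows but {len(self.channel_labels)} channel labels"
            )
        if trig.size and (np.any(np.diff(trig) <= 0) or trig[0] < 0 or trig[-1] >= data.shape[1]):
            raise ValueError("trigger_samples must be strictly increasing and in bounds")
        if self.annotations and len(self.annotations) != trig.size:
            raise ValueError("annotations must match trigger count")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "trigger_samples", trig)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class VASTable:
    """Per-subject visual-analogue fatigue scores for the 8 codes."""

    scores: "object"  # pandas.DataFrame, columns M1..M4, Ch1..Ch4

    def __post_init__(self) -> None:
        import pandas as pd

        df = self.scores
        if not isinstance(df, pd.DataFrame):
            raise TypeError("scores must be a pandas DataFrame")
        if df.isna().any().any():
            raise ValueError("VAS table must have no missing cells")
        vals = df.to_numpy(float)
        if vals.min() < 0 or vals.max() > 10:
            raise ValueError("VAS scores must lie in [0, 10]")

    def family_means(self, prefix: str) -> np.ndarray:
        """Per-subject average over one code family's 4 lagged versions."""
        cols = [c for c in self.scores.columns if c.startswith(prefix)]
        return self.scores[cols].to_numpy(float).mean(axis=1)


def make_vep_kernel(
    fs_hz: float = 600.0,
    duration_s: float = 0.25,
    shape_params: list[tuple[float, float, float, float]] | None = None,
    seed: int | None = None,
) -> VEPKernel:
    """Build a causal, decaying evoked-response kernel of unit energy.

    The kernel is a sum of damped sinusoids, each described by
    ``(freq_hz, decay_tau_s, latency_s, amplitude)`` and zero before its
    latency — a crude but adequate stand-in for the occipital impulse
    response to a single flash.  A ``seed`` jitters the component
    frequencies and latencies by a few percent, giving distinct
    "subjects"; the kernel is deterministic given the seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if shape_params is None:
        # fast occipital transients (P1/N1-like) plus a slower late wave;
        # the short decay times keep the kernel autocorrelation low beyond
        # ~80 ms so that lagged code responses remain separable
        shape_params = [
            (14.0, 0.025, 0.020, 1.0),
            (28.0, 0.035, 0.050, 0.8),
            (9.0, 0.060, 0.085, 0.6),
        ]
    params = np.asarray(shape_params, dtype=float)
    if seed is not None:
        rng = np.random.default_rng(seed)
        params = params.copy()
        params[:, 0] *= 1.0 + 0.05 * rng.standard_normal(len(params))
        params[:, 2] *= 1.0 + 0.05 * rng.standard_normal(len(params))
    n = round(duration_s * fs_hz)
    t = np.arange(n) / fs_hz
    k = np.zeros(n)
    for f, tau, t0, amp in params:
        tt = t - t0
        k += amp * np.exp(-np.clip(tt, 0, None) / tau) * np.sin(2 * np.pi * f * tt) * (tt >= 0)
    energy = float(k @ k)
    if energy == 0:
        raise ValueError("kernel is identically zero; check shape_params")
    return VEPKernel(samples=k / np.sqrt(energy), fs_hz=fs_hz)


def _code_waveform(code: BinaryCode, fs_hz: float, n_repeats: int) -> np.ndarray:
    """+/-1 bit train repeated n_repeats times, zero-order-hold sampled at fs_hz."""
    L = len(code)
    n_samples = round(fs_hz * n_repeats * L / code.rate_hz)
    bit_idx = np.floor(np.arange(n_samples) * code.rate_hz / fs_hz).astype(np.int64) % L
    return code.signed()[bit_idx]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise, unit variance per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    return pink / pink.std(axis=1, keepdims=True)


def simulate_recording(
    stimulus: StimulusSet,
    target_sequence: list[int],
    kernel: VEPKernel,
    config: SimulationConfig,
) -> EEGRecording:
    """Simulate one session: ``n_trials`` cued trials with breaks in between.

    ``target_sequence`` gives the attended target index (1-based) per
    trial and must have ``config.n_trials`` entries.  For each trial the
    target code's +/-1 waveform (``epochs_per_trial`` repeats, zero-order
    hold at ``fs_hz``) is linearly convolved with the kernel, truncated
    to the trial length, scaled per channel by ``mixing_weights`` and
    globally so the realized signal/noise power ratio over stimulation
    samples equals ``snr_db``.  Breaks carry noise only.  Deterministic
    given ``config.seed``.
    """
    if len(target_sequence) != config.n_trials:
        raise ValueError(
            f"target_sequence has {len(target_sequence)} entries, expected {config.n_trials}"
        )
    if any(not 1 <= t <= stimulus.n_targets for t in target_sequence):
        raise ValueError("target indices must be 1-based and within the stimulus set")
    config.validate_rate(stimulus.base.rate_hz)

    rate = stimulus.base.rate_hz
    L = len(stimulus.base)
    t_stim = round(config.fs_hz * config.epochs_per_trial * L / rate)
    t_break = round(config.fs_hz * config.break_s)
    n_total = config.n_trials * (t_stim + t_break)
    m = config.n_channels
    rng = np.random.default_rng(config.seed)

    # per-target clean single-channel response (shared across trials)
    responses = {}
    for idx in sorted(set(target_sequence)):
        wav = _code_waveform(stimulus.targets[idx - 1], config.fs_hz, config.epochs_per_trial)
        responses[idx] = np.convolve(wav, kernel.samples)[:t_stim]

    signal = np.zeros((m, n_total))
    triggers = np.empty(config.n_trials, dtype=np.int64)
    weights = np.asarray(config.mixing_weights, dtype=float)
    stim_mask = np.zeros(n_total, dtype=bool)
    for tr, idx in enumerate(target_sequence):
        onset = tr * (t_stim + t_break)
        triggers[tr] = onset
        signal[:, onset : onset + t_stim] = weights[:, None] * responses[idx]
        stim_mask[onset : onset + t_stim] = True

    if math.isinf(config.snr_db) and config.snr_db > 0:  # noiseless
        data = signal
    else:
        noise = np.sqrt(config.pink_fraction) * _pink_noise(rng, (m, n_total)) + np.sqrt(
            1.0 - config.pink_fraction
        ) * rng.standard_normal((m, n_total))
        noise *= config.white_sd
        if math.isinf(config.snr_db):  # -inf: noise-only control
            data = noise
        else:
            p_sig = float(np.mean(signal[:, stim_mask] ** 2))
            if p_sig == 0:
                raise ValueError("cannot set snr_db: simulated signal has zero power")
            p_noise = float(np.mean(noise[:, stim_mask] ** 2))
            gain = np.sqrt(10.0 ** (config.snr_db / 10.0) * p_noise / p_sig)
            data = noise + gain * signal

    labels = tuple(stimulus.targets[idx - 1].label for idx in target_sequence)
    return EEGRecording(
        data=data,
        fs_hz=config.fs_hz,
        trigger_samples=triggers,
        channel_labels=config.channel_labels,
        annotations=labels,
    )


def simulate_study(
    stimulus: StimulusSet,
    kernel: VEPKernel,
    config: SimulationConfig,
) -> dict[str, EEGRecording]:
    """Simulate one session per target (the per-code session protocol).

    Returns ``{target_label: recording}`` where each recording holds
    ``config.n_trials`` trials of that single target, with per-session
    independent noise seeded from ``config.seed``.
    """
    out = {}
    for i, target in enumerate(stimulus.targets, start=1):
        cfg = replace(config, seed=config.seed * stimulus.n_targets + i)
        rec = simulate_recording(stimulus, [i] * config.n_trials, kernel, cfg)
        out[target.label] = rec
    return out


def simulate_vas(
    n_subjects: int = 44,
    family_means: tuple[float, float] = (5.8152, 4.9076),
    family_sds: tuple[float, float] = (2.6207, 2.1981),
    within_subject_corr: float = 0.8,
    code_jitter_sd: float = 0.5,
    seed: int = 0,
    columns: tuple[str, ...] = ("M1", "M2", "M3", "M4", "Ch1", "Ch2", "Ch3", "Ch4"),
) -> VASTable:
    """Synthetic fatigue-score table: subjects x 8 codes, scores in [0, 10].

    Generative model: a shared subject latent u plus a family-level
    residual plus per-code jitter, with variances chosen so that the two
    per-subject family *averages* have the requested standard deviations
    and within-subject correlation (latent variance = corr * sd1 * sd2).
    Scores are clipped to [0, 10].  Defaults reproduce the observed
    fatigue contrast between m-sequence and chaotic stimulation.
    """
    if not all(0 <= mu <= 10 for mu in family_means):
        raise ValueError("family_means must lie in [0, 10]")
    if not abs(within_subject_corr) < 1:
        raise ValueError("within_subject_corr must satisfy |corr| < 1")
    sd1, sd2 = family_sds
    var_latent = within_subject_corr * sd1 * sd2
    if var_latent < 0:
        raise ValueError("negative within_subject_corr with these sds is not representable")
    var_resid = (sd1**2 - var_latent, sd2**2 - var_latent)
    var_jitter_mean = code_jitter_sd**2 / 4.0
    if any(v < var_jitter_mean - 1e-12 for v in var_resid):
        raise ValueError(
            "family sds too small for the requested correlation and code jitter"
        )
    rng = np.random.default_rng(seed)
    u = np.sqrt(var_latent) * rng.standard_normal(n_subjects)
    scores = np.empty((n_subjects, 8))
    for f in range(2):
        b_sd = np.sqrt(max(var_resid[f] - var_jitter_mean, 0.0))
        b = b_sd * rng.standard_normal(n_subjects)
        jit = code_jitter_sd * rng.standard_normal((n_subjects, 4))
        scores[:, 4 * f : 4 * f + 4] = family_means[f] + (u + b)[:, None] + jit
    import pandas as pd

    df = pd.DataFrame(np.clip(scores, 0.0, 10.0), columns=list(columns))
    df.index.name = "subject"
    return VASTable(scores=df)
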