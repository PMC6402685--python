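"""Binary modulation codes for code-modulated VEP stimulation.

Two code families are supported: classical maximal-length sequences
(m-sequences) from a linear-feedback shift register, and chaotic binary
codes derived from the logistic map with complement pairing.  Both are
presented at ``rate_hz`` bits per second (default 90), bit 0 = dark,
bit 1 = light.  Lagged targets are circular shifts of one base code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogisticMapParams",
    "BinaryCode",
    "StimulusSet",
    "CorrelationFunction",
    "AmplitudeSpectrum",
    "logistic_step",
    "generate_chaotic_code",
    "generate_m_sequence",
    "circular_shift",
    "make_stimulus_set",
    "correlate",
    "amplitude_spectrum",
]

DEFAULT_RATE_HZ = 90.0
#: Band partition (Hz) used when characterizing stimulus spectra:
#: low [0, 10), medium [10, 30], high (30, Nyquist].
BAND_EDGES_HZ = (10.0, 30.0)


@dataclass(frozen=True)
class LogisticMapParams:
    """Parameters of the logistic map ``x(i+1) = A * x(i) * (1 - x(i))``.

    ``x0`` is the initial population ratio in (0, 1); ``A`` the growth
    parameter in [0, 4] (chaotic regime roughly 3.5-4); ``threshold``
    binarizes the iterates (x > threshold emits bit 0, else bit 1).
    """

    x0: float = 0.015
    A: float = 3.882
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.x0 < 1.0:
            raise ValueError(f"x0 must lie in (0, 1), got {self.x0}")
        if not 0.0 <= self.A <= 4.0:
            raise ValueError(f"A must lie in [0, 4], got {self.A}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass(frozen=True)
class BinaryCode:
    """An ordered 0/1 sequence with a presentation rate (bits/second)."""

    bits: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    label: str = ""

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or bits.size == 0:
            raise ValueError("bits must be a non-empty 1-D sequence")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "bits", bits)
        self.bits.setflags(write=False)

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def length(self) -> int:
        return len(self)

    @property
    def duration_s(self) -> float:
        """Presentation time of one code period (one epoch), seconds."""
        return len(self) / self.rate_hz

    def signed(self) -> np.ndarray:
        """Bits mapped to +/-1 (0 -> -1, 1 -> +1), float array."""
        return self.bits.astype(float) * 2.0 - 1.0


@dataclass(frozen=True)
class StimulusSet:
    """A base code and its circularly lagged targets.

    Target ``i`` (1-based) is the base shifted by ``(i-1)*shift_step_bits``
    bits; the temporal lag step is ``shift_step_bits / rate_hz`` seconds.
    """

    base: BinaryCode
    n_targets: int = 4
    shift_step_bits: int = 8
    targets: tuple[BinaryCode, ...] = field(default=())

    @property
    def shift_step_s(self) -> float:
        return self.shift_step_bits / self.base.rate_hz

    def __len__(self) -> int:
        return self.n_targets


@dataclass(frozen=True)
class CorrelationFunction:
    """Normalized correlation values over integer bit lags."""

    lags: np.ndarray
    values: np.ndarray
    mode: str = "circular"

    @property
    def peak_lag(self) -> int:
        return int(self.lags[int(np.argmax(self.values))])


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a bit train, with band energies.

    ``band_energy`` partitions the total spectral energy into the low
    [0, 10), medium [10, 30] and high (30, Nyquist] Hz bands.
    """

    freqs_hz: np.ndarray
    amplitudes: np.ndarray
    band_edges_hz: tuple[float, float] = BAND_EDGES_HZ
    band_energy: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def total_energy(self) -> float:
        return float(sum(self.band_energy))

    def band_fractions(self) -> tuple[float, float, float]:
        tot = self.total_energy
        return tuple(e / tot for e in self.band_energy)  # type: ignore[return-value]


def logistic_step(x: float, A: float) -> float:
    """One iterate of the logistic map, ``A * x * (1 - x)``.

    Raises ``ValueError`` naming the offending parameter when ``x`` is
    outside [0, 1] or ``A`` outside [0, 4].
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got x={x}")
    if not 0.0 <= A <= 4.0:
        raise ValueError(f"A must lie in [0, 4], got A={A}")
    return A * x * (1.0 - x)


def generate_chaotic_code(
    params: LogisticMapParams = LogisticMapParams(),
    length: int = 31,
    n_iterations: int = 17,
    rate_hz: float = DEFAULT_RATE_HZ,
    label: str = "Ch1",
) -> BinaryCode:
    """Generate a chaotic binary code from the logistic map.

    Each map iterate emits a bit C(n) (0 if x > threshold, else 1)
    immediately followed by its one's complement C(n+1) = 1 - C(n);
    ``n_iterations`` iterates therefore yield ``2*n_iterations`` raw bits,
    of which the first ``length`` are returned.  The complement pairing
    balances the code and pushes its spectral energy toward high
    frequencies, which is what makes the chaotic code less visually
    fatiguing than an m-sequence at the same presentation rate.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if length > 2 * n_iterations:
        raise ValueError(
            f"length {length} exceeds the {2 * n_iterations} raw bits produced by "
            f"{n_iterations} iterations; increase n_iterations to at least "
            f"{-(-length // 2)}"
        )
    x = params.x0
    raw = np.empty(2 * n_iterations, dtype=np.int8)
    for i in range(n_iterations):
        x = logistic_step(x, params.A)
        c = 0 if x > params.threshold else 1
        raw[2 * i] = c
        raw[2 * i + 1] = 1 - c
    return BinaryCode(raw[:length], rate_hz=rate_hz, label=label)


def generate_m_sequence(
    order: int = 5,
    taps: tuple[int, ...] = (5, 2),
    seed: tuple[int, ...] | None = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    label: str = "M1",
) -> BinaryCode:
    """Generate a maximal-length sequence from a Fibonacci LFSR.

    ``taps`` are the 1-based register positions entering the XOR feedback
    (default (5, 2), the primitive polynomial x^5 + x^2 + 1); ``seed`` is
    the initial register state, most-significant stage first (default
    all ones).  The output has period ``2**order - 1`` when the taps are
    primitive; non-primitive taps produce a shorter period, which is
    reported with a warning.
    """
    if order < 1:
        raise ValueError("order must be positive")
    state = [1] * order if seed is None else [int(b) for b in seed]
    if len(state) != order:
        raise ValueError(f"seed must have {order} elements, got {len(state)}")
    if not any(state):
        raise ValueError("seed register state must be nonzero")
    if any(t < 1 or t > order for t in taps):
        raise ValueError(f"taps must be 1-based positions within 1..{order}")

    period = 2**order - 1
    initial = tuple(state)
    out = np.empty(period, dtype=np.int8)
    for n in range(period):
        out[n] = state[-1]
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = [fb] + state[:-1]
    if tuple(state) != initial:
        warnings.warn(
            f"taps {taps} are not primitive for order {order}: the register did "
            f"not return to its initial state after {period} steps, so the "
            "sequence period is shorter than maximal",
            stacklevel=2,
        )
    return BinaryCode(out, rate_hz=rate_hz, label=label)


def circular_shift(code: BinaryCode, shift_bits: int) -> BinaryCode:
    """Circularly delay a code by ``shift_bits`` (element j <- element (j - shift) mod L)."""
    bits = np.roll(code.bits, shift_bits % len(code))
    label = f"{code.label}>>{shift_bits % len(code)}" if code.label else ""
    return BinaryCode(bits, rate_hz=code.rate_hz, label=label)


def make_stimulus_set(
    base: BinaryCode,
    n_targets: int = 4,
    shift_step_bits: int = 8,
    label_prefix: str | None = None,
) -> StimulusSet:
    """Build the lagged target set: target i shifted by (i-1)*shift_step_bits bits.

    Raises if any two target shifts coincide modulo the code length.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be positive")
    if shift_step_bits < 1:
        raise ValueError("shift_step_bits must be positive")
    shifts = [(i * shift_step_bits) % len(base) for i in range(n_targets)]
    if len(set(shifts)) != n_targets:
        raise ValueError(
            f"target shifts {shifts} are not distinct modulo the code length {len(base)}"
        )
    prefix = label_prefix if label_prefix is not None else (base.label or "T")
    targets = tuple(
        BinaryCode(np.roll(base.bits, s), rate_hz=base.rate_hz, label=f"{prefix[:-1] or prefix}{i + 1}")
        for i, s in enumerate(shifts)
    )
    return StimulusSet(
        base=base, n_targets=n_targets, shift_step_bits=shift_step_bits, targets=targets
    )


def correlate(
    a: BinaryCode,
    b: BinaryCode | None = None,
    mode: str = "circular",
    mapping: str = "pm1",
) -> CorrelationFunction:
    """Normalized (cross-)correlation of two codes over integer bit lags.

    Bits are mapped 0 -> -1, 1 -> +1 by default (``mapping='pm1'``), which
    is what gives the m-sequence its classical two-valued {1, -1/L}
    circular autocorrelation; ``mapping='raw'`` keeps the 0/1 values.
    Values are normalized by the geometric mean of the two zero-lag
    autocorrelations, so an autocorrelation is exactly 1 at lag 0.
    A positive lag k means ``b`` leads: value[k] = sum_t a[t] * b[t + k];
    for ``b = circular_shift(a, k0)`` the peak sits at lag k0.
    """
    if b is None:
        b = a
    if mapping == "pm1":
        xa, xb = a.signed(), b.signed()
    elif mapping == "raw":
        xa, xb = a.bits.astype(float), b.bits.astype(float)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    norm = np.sqrt(float(xa @ xa) * float(xb @ xb))
    if mode == "circular":
        if len(a) != len(b):
            raise ValueError(
                f"circular correlation requires equal lengths, got {len(a)} and {len(b)}"
            )
        L = len(a)
        # value[k] = sum_t a[t] * b[(t + k) mod L], computed via FFT
        vals = np.fft.ifft(np.conj(np.fft.fft(xa)) * np.fft.fft(xb)).real
        lags = np.arange(L)
    elif mode == "linear":
        vals = np.correlate(xb, xa, mode="full")
        lags = np.arange(-(len(a) - 1), len(b))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CorrelationFunction(lags=lags, values=vals / norm, mode=mode)


def amplitude_spectrum(code: BinaryCode) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of one code period sampled at rate_hz.

    The raw 0/1 bit train over a single period is transformed with a
    rectangular window.  ``band_energy`` partitions the one-sided spectral
    power (DC counted once, other bins twice) into the low/medium/high
    bands; by Parseval the three components sum to the mean squared bit
    value.
    """
    x = code.bits.astype(float)
    N = len(x)
    X = np.fft.rfft(x) / N
    freqs = np.fft.rfftfreq(N, d=1.0 / code.rate_hz)
    mult = np.full(X.size, 2.0)
    mult[0] = 1.0
    if N % 2 == 0:
        mult[-1] = 1.0
    amps = mult * np.abs(X)
    power = mult * np.abs(X) ** 2
    lo_edge, hi_edge = BAND_EDGES_HZ
    low = float(power[freqs < lo_edge].sum())
    med = float(power[(freqs >= lo_edge) & (freqs <= hi_edge)].sum())
    high = float(power[freqs > hi_edge].sum())
    return AmplitudeSpectrum(
        freqs_hz=freqs,
        amplitudes=amps,
        band_edges_hz=BAND_EDGES_HZ,
        band_energy=(low, med, high),
    )
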