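"""Stimulus-code generation, shifting, correlation and spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvep.codes import (
    BinaryCode,
    LogisticMapParams,
    amplitude_spectrum,
    circular_shift,
    correlate,
    generate_chaotic_code,
    generate_m_sequence,
    logistic_step,
    make_stimulus_set,
)


def logistic_bits_oracle(x0, A, threshold, n_iter):
    """Independent brute-force iteration of the map with complement pairing."""
    bits = []
    x = x0
    for _ in range(n_iter):
        x = A * x * (1 - x)
        c = 0 if x > threshold else 1
        bits.extend([c, 1 - c])
    return bits


def lfsr_oracle(order, taps, seed):
    """Step-by-step Fibonacci LFSR simulation, independent of the library."""
    state = list(seed)
    out = []
    for _ in range(2**order - 1):
        out.append(state[-1])
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = [fb] + state[:-1]
    return out


class TestLogisticStep:
    @pytest.mark.parametrize(
        "x, A, expected",
        [(0.0, 3.882, 0.0), (1.0, 3.882, 0.0), (0.15, 3.882, 0.494955)],
    )
    def test_values(self, x, A, expected):
        assert logistic_step(x, A) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("x, A, bad", [(-0.1, 3.0, "x"), (1.5, 3.0, "x"), (0.5, 4.5, "A"), (0.5, -1.0, "A")])
    def test_domain_errors_name_parameter(self, x, A, bad):
        with pytest.raises(ValueError, match=bad):
            logistic_step(x, A)


class TestChaoticCode:
    def test_default_is_31_bits_matching_bruteforce_oracle(self, chaotic_code):
        oracle = logistic_bits_oracle(0.015, 3.882, 0.5, 17)
        assert len(chaotic_code) == 31
        assert chaotic_code.bits.tolist() == oracle[:31]
        assert chaotic_code.bits[:6].tolist() == [1, 0, 1, 0, 0, 1]

    def test_complement_pair_structure(self):
        code = generate_chaotic_code(length=34)
        pairs = code.bits.reshape(-1, 2)
        assert np.all(pairs.sum(axis=1) == 1)

    def test_balance_of_truncated_code(self, chaotic_code):
        assert int(chaotic_code.bits.sum()) in (15, 16)

    def test_deterministic(self):
        a = generate_chaotic_code(LogisticMapParams(x0=0.3, A=3.9))
        b = generate_chaotic_code(LogisticMapParams(x0=0.3, A=3.9))
        assert np.array_equal(a.bits, b.bits)

    def test_length_exceeding_budget_advises_more_iterations(self):
        with pytest.raises(ValueError, match="n_iterations"):
            generate_chaotic_code(length=35, n_iterations=17)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LogisticMapParams(x0=0.0)
        with pytest.raises(ValueError):
            LogisticMapParams(A=4.5)


class TestMSequence:
    def test_length_and_balance(self, mseq_code):
        assert len(mseq_code) == 31
        assert int(mseq_code.bits.sum()) == 16

    def test_matches_shift_register_oracle(self, mseq_code):
        assert mseq_code.bits.tolist() == lfsr_oracle(5, (5, 2), [1] * 5)

    def test_two_valued_autocorrelation_brute_force(self, mseq_code):
        x = mseq_code.signed()
        L = len(x)
        for lag in range(1, L):
            val = float(x @ np.roll(x, lag)) / L
            assert val == pytest.approx(-1 / 31, abs=1e-12)

    def test_all_zero_seed_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            generate_m_sequence(seed=(0, 0, 0, 0, 0))

    def test_non_primitive_taps_warn(self):
        # x^5 + x + 1 factors over GF(2); period is shorter than 31
        with pytest.warns(UserWarning, match="not primitive"):
            generate_m_sequence(taps=(5, 1))


class TestCircularShift:
    def test_identity_and_full_rotation(self, chaotic_code):
        assert np.array_equal(circular_shift(chaotic_code, 0).bits, chaotic_code.bits)
        assert np.array_equal(
            circular_shift(chaotic_code, len(chaotic_code)).bits, chaotic_code.bits
        )

    @settings(deadline=None, derandomize=True)
    @given(st.integers(-100, 100), st.integers(-100, 100))
    def test_shifts_compose_additively(self, s1, s2):
        code = generate_chaotic_code()
        via_two = circular_shift(circular_shift(code, s1), s2)
        direct = circular_shift(code, s1 + s2)
        assert np.array_equal(via_two.bits, direct.bits)

    def test_shift_delays_elements(self, mseq_code):
        shifted = circular_shift(mseq_code, 8)
        L = len(mseq_code)
        for j in range(L):
            assert shifted.bits[j] == mseq_code.bits[(j - 8) % L]


class TestStimulusSet:
    def test_default_four_targets_at_8bit_steps(self, chaotic_set, chaotic_code):
        assert [t.label for t in chaotic_set.targets] == ["Ch1", "Ch2", "Ch3", "Ch4"]
        for i, tgt in enumerate(chaotic_set.targets):
            assert np.array_equal(tgt.bits, np.roll(chaotic_code.bits, 8 * i))
        assert np.array_equal(chaotic_set.targets[0].bits, chaotic_code.bits)

    def test_single_target_is_base(self, chaotic_code):
        ss = make_stimulus_set(chaotic_code, n_targets=1)
        assert len(ss.targets) == 1
        assert np.array_equal(ss.targets[0].bits, chaotic_code.bits)

    def test_time_step_truncates_to_88ms(self, chaotic_set):
        assert chaotic_set.shift_step_s == pytest.approx(8 / 90)
        assert int(chaotic_set.shift_step_s * 1000) / 1000 == 0.088

    def test_coincident_shifts_rejected(self, chaotic_code):
        with pytest.raises(ValueError, match="distinct"):
            make_stimulus_set(chaotic_code, n_targets=2, shift_step_bits=31)


class TestCorrelate:
    def test_autocorrelation_is_one_at_zero_lag(self, chaotic_code, mseq_code):
        for code in (chaotic_code, mseq_code):
            cf = correlate(code, code)
            assert cf.values[0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.abs(cf.values) <= 1 + 1e-12)

    def test_mseq_circular_autocorrelation_two_valued(self, mseq_code):
        cf = correlate(mseq_code, mseq_code)
        assert cf.values[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(cf.values[1:], -1 / 31, atol=1e-12)

    @pytest.mark.parametrize("shift", [1, 8, 16, 30])
    def test_peak_at_imposed_shift(self, chaotic_code, mseq_code, shift):
        for code in (chaotic_code, mseq_code):
            cf = correlate(code, circular_shift(code, shift))
            assert cf.peak_lag == shift

    def test_length_mismatch_rejected(self, chaotic_code):
        other = BinaryCode(np.array([0, 1, 0]))
        with pytest.raises(ValueError, match="equal lengths"):
            correlate(chaotic_code, other)

    def test_raw_mapping_differs_from_signed(self, mseq_code):
        signed = correlate(mseq_code, mseq_code, mapping="pm1")
        raw = correlate(mseq_code, mseq_code, mapping="raw")
        assert raw.values[0] == pytest.approx(1.0)
        assert not np.allclose(signed.values[1:], raw.values[1:])


class TestAmplitudeSpectrum:
    def test_constant_code_is_pure_dc(self):
        spec = amplitude_spectrum(BinaryCode(np.ones(31, dtype=int)))
        assert spec.band_energy[0] == pytest.approx(1.0)
        assert spec.band_energy[1] == pytest.approx(0.0, abs=1e-15)
        assert spec.band_energy[2] == pytest.approx(0.0, abs=1e-15)
        assert np.all(spec.amplitudes[1:] < 1e-12)

    @pytest.mark.parametrize("family", ["chaotic", "mseq"])
    def test_parseval_band_partition(self, family, chaotic_code, mseq_code):
        code = chaotic_code if family == "chaotic" else mseq_code
        spec = amplitude_spectrum(code)
        total = float(np.mean(code.bits.astype(float) ** 2))
        assert sum(spec.band_energy) == pytest.approx(total, rel=1e-9)

    def test_energy_partition_invariant_to_circular_shift(self, chaotic_code):
        a = amplitude_spectrum(chaotic_code)
        b = amplitude_spectrum(circular_shift(chaotic_code, 13))
        np.testing.assert_allclose(a.band_energy, b.band_energy, rtol=1e-9)

    def test_chaotic_code_has_larger_high_band_fraction(self, chaotic_code, mseq_code):
        ch = amplitude_spectrum(chaotic_code).band_fractions()
        ms = amplitude_spectrum(mseq_code).band_fractions()
        assert ch[2] > ms[2]

    def test_frequencies_span_zero_to_nyquist(self, chaotic_code):
        spec = amplitude_spectrum(chaotic_code)
        assert spec.freqs_hz[0] == 0.0
        assert np.all(np.diff(spec.freqs_hz) > 0)
        assert spec.freqs_hz[-1] <= chaotic_code.rate_hz / 2
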