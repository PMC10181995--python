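"""Comb filter difference equation and closed-form response analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgcomb import (
    FFCParams,
    Signal,
    amplitude_response,
    cutoff_frequencies,
    ffc_apply,
    ffc_delay,
    null_frequencies,
)


class TestDelayDesign:
    @pytest.mark.parametrize(
        "fs, f_pli, expected",
        [(1000, 50, 20), (1200, 60, 20), (500, 50, 10), (1200, 50, 24)],
    )
    def test_integer_ratio(self, fs, f_pli, expected):
        assert ffc_delay(fs, f_pli) == expected

    def test_non_integer_ratio_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="admissible sampling frequencies"):
            ffc_delay(1000, 60)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ffc_delay(0, 50)


class TestApply:
    def test_impulse_response_is_two_taps(self):
        x = Signal(np.r_[1.0, np.zeros(39)], 1000.0)
        y = ffc_apply(x, FFCParams(N=20, alpha=-1))
        expected = np.zeros(40)
        expected[0], expected[20] = 1.0, -1.0
        np.testing.assert_array_equal(y.samples, expected)

    def test_constant_input_cancelled_after_transient(self):
        x = Signal(np.full(100, 3.7), 1000.0)
        y = ffc_apply(x, FFCParams(N=20, alpha=-1))
        np.testing.assert_array_equal(y.samples[:20], np.full(20, 3.7))
        np.testing.assert_array_equal(y.samples[20:], np.zeros(80))

    def test_matched_sinusoid_nulled_in_steady_state(self, make_sinusoid):
        y = ffc_apply(make_sinusoid(50.0), FFCParams(N=20, alpha=-1, fs=1000))
        assert np.max(np.abs(y.samples[20:])) < 1e-9

    def test_equals_direct_convolution_oracle(self, rng):
        """The recursion-free oracle: convolve with {1 at lag 0, alpha at lag N}."""
        for alpha in (-1.0, 1.0, 0.35):
            x = rng.standard_normal(10_000)
            n = 37
            kernel = np.zeros(n + 1)
            kernel[0], kernel[n] = 1.0, alpha
            expected = np.convolve(x, kernel)[: len(x)]
            y = ffc_apply(Signal(x, 1000.0), FFCParams(N=n, alpha=alpha))
            assert np.max(np.abs(y.samples - expected)) <= 1e-12

    def test_offset_invariance_zero_dc_gain(self, rng):
        """Adding any constant offset leaves the alpha=-1 output unchanged for k >= N."""
        x = rng.standard_normal(2000)
        p = FFCParams(N=20, alpha=-1)
        y0 = ffc_apply(Signal(x, 1000.0), p).samples
        y1 = ffc_apply(Signal(x + 123.456, 1000.0), p).samples
        np.testing.assert_allclose(y0[20:], y1[20:], atol=1e-12)


class TestAmplitudeResponse:
    @pytest.mark.parametrize(
        "f_norm, N, alpha, expected",
        [
            (0.050, 20, -1, 0.0),           # 50 Hz null at fs=1000
            (0.025, 20, -1, 2.0),           # peak midway between nulls
            (0.0125, 20, -1, np.sqrt(2.0)),  # -3 dB point (12.5 Hz at fs=1000)
            (0.025, 20, 1, 0.0),            # alpha=+1 null at fs/(2N)
            (0.0, 20, 1, 2.0),              # alpha=+1 passes DC at peak gain
        ],
    )
    def test_closed_form_values(self, f_norm, N, alpha, expected):
        assert amplitude_response(f_norm, N, alpha) == pytest.approx(expected, abs=1e-12)

    def test_general_alpha_rejected(self):
        with pytest.raises(ValueError):
            amplitude_response(0.1, 20, 0.5)

    def test_peak_gain_is_two_on_dense_grid(self):
        f = np.linspace(0, 0.5, 100_001)
        h = amplitude_response(f, 20, -1)
        assert h.max() <= 2.0 + 1e-12
        # attained midway between adjacent nulls (0.025 = half of 1/N)
        assert h[np.argmax(h)] == pytest.approx(2.0, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=0.45))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_periodicity_in_one_over_n(self, f_norm):
        n = 20
        assert amplitude_response(f_norm, n, -1) == pytest.approx(
            amplitude_response(f_norm + 1.0 / n, n, -1), abs=1e-9
        )

    def test_steady_state_sinusoid_gain_matches_closed_form(self, make_sinusoid):
        """Empirical amplitude ratio after the transient equals 2|sin(pi N f/fs)|."""
        rng = np.random.default_rng(7)
        p = FFCParams(N=20, alpha=-1, fs=1000)
        for f in rng.uniform(1.0, 499.0, size=20):
            x = make_sinusoid(f, duration=4.0)
            y = ffc_apply(x, p).samples[1000:]
            t = (np.arange(len(x)) / 1000.0)[1000:]
            basis = np.c_[np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
            coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
            measured = float(np.hypot(*coef))
            assert measured == pytest.approx(
                amplitude_response(f / 1000.0, 20, -1), abs=1e-6
            )


class TestNullsAndCutoffs:
    def test_nulls_alpha_minus_one_hit_every_harmonic(self):
        nulls = null_frequencies(FFCParams(N=20, alpha=-1, fs=1000), 500)
        np.testing.assert_allclose(nulls, np.arange(0, 501, 50))

    def test_nulls_alpha_plus_one_are_odd_half_multiples(self):
        nulls = null_frequencies(FFCParams(N=20, alpha=1, fs=1000), 200)
        np.testing.assert_allclose(nulls, [25, 75, 125, 175])

    def test_degenerate_single_tap_delay(self):
        nulls = null_frequencies(FFCParams(N=1, alpha=-1, fs=100), 50)
        np.testing.assert_allclose(nulls, [0])

    def test_cutoffs_at_quarter_offsets(self):
        cut = cutoff_frequencies(FFCParams(N=20, alpha=-1, fs=1000), 100)
        np.testing.assert_allclose(cut, [12.5, 37.5, 62.5, 87.5])

    def test_cutoff_for_60hz_mains_sampling(self):
        cut = cutoff_frequencies(FFCParams(N=20, alpha=-1, fs=1200), 20)
        np.testing.assert_allclose(cut, [15.0])

    def test_every_cutoff_equidistant_from_nearest_null(self):
        p = FFCParams(N=20, alpha=-1, fs=1000)
        nulls = null_frequencies(p, 500)
        for c in cutoff_frequencies(p, 500):
            assert np.min(np.abs(nulls - c)) == pytest.approx(1000 / (4 * 20), abs=1e-9)

    def test_cutoff_requires_alpha_minus_one(self):
        with pytest.raises(ValueError):
            cutoff_frequencies(FFCParams(N=20, alpha=1, fs=1000), 100)
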