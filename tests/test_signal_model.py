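"""Curve construction: differences, indicators, adaptive weights, accumulators."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dgei import (
    DgeiParams,
    GaitSignal,
    InvalidInputError,
    adaptive_weights,
    dgei_curves,
    first_difference,
    indicator,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def brute_force_curves(values, w, bar, alpha, beta, fs, mode):
    """Naive double-loop evaluation of the windowed accumulators (test oracle)."""
    diff = [values[k] - values[k - 1] for k in range(1, len(values))]
    pos, neg = [], []
    for i in range(len(diff)):
        p = n = 0.0
        for k in range(max(0, i - w), i + 1):
            term = alpha[k] * diff[k] + beta[k] * diff[k] * fs
            if diff[k] > bar:
                p += term
            if (diff[k] < -bar) if mode == "symmetric" else (diff[k] <= bar):
                n += term
        pos.append(p)
        neg.append(n)
    return np.array(pos), np.array(neg)


class TestFirstDifference:
    @pytest.mark.parametrize(
        "values, expected",
        [([1, 1, 1, 1], [0, 0, 0]), ([0, 2, 5, 3], [2, 3, -2])],
    )
    def test_examples(self, values, expected):
        assert first_difference(GaitSignal(values)).tolist() == expected

    @given(st.lists(finite_floats, min_size=1, max_size=50))
    def test_inverts_cumulative_sum(self, deltas):
        signal = GaitSignal(np.concatenate([[0.0], np.cumsum(deltas)]))
        np.testing.assert_allclose(
            first_difference(signal), deltas, rtol=1e-9, atol=1e-6
        )

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            first_difference(GaitSignal([1.0]))


class TestIndicator:
    @pytest.mark.parametrize(
        "dy, bar, mode, expected",
        [
            (10, 9, "verbatim", (1, 0)),
            (10, 9, "symmetric", (1, 0)),
            (0, 0, "verbatim", (0, 1)),  # strict inequality on the positive branch
            (0, 0, "symmetric", (0, 0)),
            (-10, 9, "symmetric", (0, 1)),
            (-10, 9, "verbatim", (0, 1)),
            (5, 9, "symmetric", (0, 0)),  # small positive change: neither branch
            (5, 9, "verbatim", (0, 1)),  # literal complement routes it negative
        ],
    )
    def test_branch_table(self, dy, bar, mode, expected):
        assert indicator(dy, bar, mode) == expected

    def test_negative_bar_rejected(self):
        with pytest.raises(InvalidInputError):
            indicator(1.0, -0.5)


class TestAdaptiveWeights:
    def test_ratio_example(self):
        # sigma of [-3, 3] is 3; mean |rate| of [1, 1] is 1 -> alpha 0.75
        alpha, beta = adaptive_weights([-3.0, 3.0], [1.0, 1.0])
        assert alpha == pytest.approx(0.75)
        assert beta == pytest.approx(0.25)

    def test_equal_statistics_split_evenly(self):
        alpha, beta = adaptive_weights([-2.0, 2.0], [2.0, 2.0])
        assert alpha == beta == pytest.approx(0.5)

    @given(st.lists(finite_floats, min_size=2, max_size=30))
    def test_weights_normalize(self, diffs):
        import warnings

        rates = [60.0 * d for d in diffs]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            alpha, beta = adaptive_weights(diffs, rates)
        assert 0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0
        assert alpha + beta == pytest.approx(1.0)

    def test_degenerate_history_warns_and_splits(self):
        with pytest.warns(RuntimeWarning):
            assert adaptive_weights([0.0, 0.0], [0.0, 0.0]) == (0.5, 0.5)


class TestDgeiCurves:
    def test_constant_signal_is_silent(self):
        curves = dgei_curves(GaitSignal(np.full(50, 3.0)), DgeiParams(bar=1.0))
        assert np.all(curves.pos == 0.0)
        assert np.all(curves.neg == 0.0)

    def test_ramp_closed_form(self):
        # slope s > bar with alpha=1, beta=0: every window term equals s, and
        # the inclusive window k = i-w..i holds w+1 terms once full.
        s, w = 5.0, 3
        signal = GaitSignal(s * np.arange(30.0))
        params = DgeiParams(
            window_w=w, bar=1.0, alpha_beta_mode="fixed", fixed_alpha=1.0, fixed_beta=0.0
        )
        curves = dgei_curves(signal, params)
        np.testing.assert_allclose(curves.pos[w:], (w + 1) * s)
        # warm-up frames use the growing partial window
        np.testing.assert_allclose(curves.pos[:w], s * np.arange(1, w + 1))

    @pytest.mark.parametrize("mode", ["symmetric", "verbatim"])
    @pytest.mark.parametrize("alpha_beta", ["fixed", "running"])
    def test_matches_brute_force(self, rng, mode, alpha_beta):
        for _ in range(20):
            n = int(rng.integers(30, 120))
            w = int(rng.integers(1, 15))
            bar = float(rng.uniform(0, 2))
            values = rng.normal(0, 3, n)
            if alpha_beta == "fixed":
                a = float(rng.uniform(0, 1))
                params = DgeiParams(window_w=w, bar=bar, alpha_beta_mode="fixed",
                                    fixed_alpha=a, fixed_beta=1 - a,
                                    indicator_mode=mode)
            else:
                params = DgeiParams(window_w=w, bar=bar, indicator_mode=mode)
            signal = GaitSignal(values)
            curves = dgei_curves(signal, params)
            pos, neg = brute_force_curves(values, w, bar, curves.alpha, curves.beta,
                                          signal.sample_rate_hz, mode)
            np.testing.assert_allclose(curves.pos, pos, atol=1e-9)
            np.testing.assert_allclose(curves.neg, neg, atol=1e-9)

    def test_scale_covariance(self, rng):
        values = rng.normal(0, 2, 80)
        params = DgeiParams(window_w=5, bar=0.0, alpha_beta_mode="fixed",
                            fixed_alpha=0.3, fixed_beta=0.7, indicator_mode="symmetric")
        base = dgei_curves(GaitSignal(values), params)
        scaled = dgei_curves(GaitSignal(4.0 * values), params)
        np.testing.assert_allclose(scaled.pos, 4.0 * base.pos, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(scaled.neg, 4.0 * base.neg, rtol=1e-9, atol=1e-9)

    def test_sign_decomposition_at_zero_bar(self, rng):
        values = rng.normal(0, 2, 100)
        params = DgeiParams(window_w=8, bar=0.0, alpha_beta_mode="fixed",
                            fixed_alpha=0.5, fixed_beta=0.5, indicator_mode="symmetric")
        signal = GaitSignal(values)
        curves = dgei_curves(signal, params)
        terms = curves.alpha * curves.diff + curves.beta * curves.rate
        from dgei.signal_model import _window_sum

        full = _window_sum(terms, params.window_w)
        np.testing.assert_allclose(curves.pos + curves.neg, full, atol=1e-9)

    def test_running_alpha_beta_normalized(self, rng):
        curves = dgei_curves(GaitSignal(rng.normal(0, 3, 200)), DgeiParams())
        np.testing.assert_allclose(curves.alpha + curves.beta, 1.0, atol=1e-12)
        assert np.all((curves.alpha >= 0) & (curves.alpha <= 1))

    def test_positive_curve_leads_raw_pulse(self):
        # on a smooth pulse the accumulator crests at or before the raw peak
        t = np.arange(120)
        pulse = 30.0 * np.exp(-0.5 * ((t - 60) / 8.0) ** 2)
        curves = dgei_curves(GaitSignal(pulse), DgeiParams(bar=0.2))
        lead = 60 - (int(np.argmax(curves.pos)) + curves.frame_offset)
        assert lead >= 0

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            dgei_curves(GaitSignal(np.zeros(5)), DgeiParams(window_w=10))

    def test_fixed_weights_must_normalize(self):
        with pytest.raises(InvalidInputError):
            DgeiParams(alpha_beta_mode="fixed", fixed_alpha=0.7, fixed_beta=0.7)
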