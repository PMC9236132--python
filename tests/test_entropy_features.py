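import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import apen_oracle, pen_oracle, sampen_oracle, sscen_oracle
from emodyn.entropy_features import (EntropyParams, UndefinedEntropyError,
                                     approximate_entropy, permutation_entropy,
                                     sample_entropy, sliding_feature_series,
                                     state_space_correlation_entropy)
from emodyn.preprocess import EEGRecording


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.ones(50), m=2, F=0.2) == pytest.approx(0.0)

    def test_alternating_series_matches_direct_count(self):
        x = np.array([1.0, -1.0] * 25)
        r = 0.5
        got = approximate_entropy(x, m=2, F=r / x.std())
        assert got == pytest.approx(apen_oracle(x, 2, r), abs=1e-12)

    def test_white_noise_matches_oracle(self, rng):
        x = rng.standard_normal(1000)
        r = 0.2 * x.std()
        got = approximate_entropy(x, m=2, F=0.2)
        assert abs(got - apen_oracle(x, 2, r)) < 0.05

    def test_length_precondition(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.ones(3), m=2)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.ones(40), m=2, F=0.2) == pytest.approx(0.0)

    def test_periodic_matches_direct_count(self):
        x = np.array([1.0, 2.0] * 50)
        r = 0.3
        got = sample_entropy(x, m=2, F=r / x.std())
        assert got == pytest.approx(sampen_oracle(x, 2, r), abs=1e-12)

    def test_length_invariance_for_periodic_pattern(self):
        short = np.array([1.0, 2.0] * 50)
        long = np.array([1.0, 2.0] * 200)
        a = sample_entropy(short, m=2, F=0.3 / short.std())
        b = sample_entropy(long, m=2, F=0.3 / long.std())
        assert abs(a - b) < 1e-9

    def test_no_matches_is_undefined_not_large(self):
        x = 10.0 ** np.arange(12)  # every template isolated at tiny r
        with pytest.raises(UndefinedEntropyError):
            sample_entropy(x, m=2, F=1e-9)


class TestPermutationEntropy:
    def test_monotone_series_is_zero(self):
        assert permutation_entropy(np.arange(30.0), D=4) == pytest.approx(0.0)

    def test_seven_point_worked_example(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        expected = -(4 / 6) * np.log2(4 / 6) - (2 / 6) * np.log2(2 / 6)
        assert permutation_entropy(x, D=2) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9183, abs=5e-5)

    def test_random_series_approaches_log2_dfactorial(self, rng):
        x = rng.random(100_000)
        assert abs(permutation_entropy(x, D=3) - np.log2(6)) < 0.05

    def test_bound_log2_d_factorial(self, rng):
        import math
        for D in (2, 3, 4):
            x = rng.standard_normal(300)
            assert permutation_entropy(x, D) <= np.log2(math.factorial(D)) + 1e-12


class TestStateSpaceCorrelationEntropy:
    def test_constant_series_is_zero(self):
        assert state_space_correlation_entropy(np.full(50, 3.0), D=3, K=8) == 0.0

    def test_single_bin_is_zero(self, rng):
        assert state_space_correlation_entropy(rng.standard_normal(100), D=3, K=1) == 0.0

    def test_matches_independent_oracle(self, rng):
        x = rng.standard_normal(500)
        got = state_space_correlation_entropy(x, D=3, K=8)
        assert got == pytest.approx(sscen_oracle(x, 3, 8), abs=1e-10)

    def test_bounded_by_log2_k(self, rng):
        for K in (4, 16):
            got = state_space_correlation_entropy(rng.standard_normal(300), D=3, K=K)
            assert got <= np.log2(K) + 1e-12


class TestAffineInvariance:
    """SD-relative tolerances and range-relative bins make every estimator
    invariant under x -> a*x + b with a > 0."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0),
           seed=st.integers(0, 10_000))
    def test_all_estimators(self, a, b, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        y = a * x + b
        assert approximate_entropy(y, 2, 0.2) == pytest.approx(
            approximate_entropy(x, 2, 0.2), abs=1e-8)
        assert sample_entropy(y, 2, 0.2) == pytest.approx(
            sample_entropy(x, 2, 0.2), abs=1e-8)
        assert permutation_entropy(y, 3) == pytest.approx(
            permutation_entropy(x, 3), abs=1e-10)
        assert state_space_correlation_entropy(y, 3, 16) == pytest.approx(
            state_space_correlation_entropy(x, 3, 16), abs=1e-8)


class TestSlidingFeatureSeries:
    def make_rec(self, data, fs=125.0):
        return EEGRecording(data, fs, [f"C{i}" for i in range(data.shape[0])])

    def test_window_count(self, rng):
        rec = self.make_rec(rng.standard_normal((2, int(300 * 125))))
        fs = sliding_feature_series(rec, ("pen",), EntropyParams(window=5.0))
        assert fs.n_windows == 60

    def test_constant_signal_zero_apen(self):
        rec = self.make_rec(np.ones((1, 1250)))
        fs = sliding_feature_series(rec, ("apen",), EntropyParams(window=5.0))
        np.testing.assert_allclose(fs.values, 0.0, atol=1e-12)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.standard_normal((3, 1250))
        perm = [2, 0, 1]
        f1 = sliding_feature_series(self.make_rec(data), ("pen",))
        f2 = sliding_feature_series(self.make_rec(data[perm]), ("pen",))
        np.testing.assert_array_equal(f2.values, f1.values[:, perm, :])

    def test_window_too_short_for_estimator(self, rng):
        rec = self.make_rec(rng.standard_normal((1, 1250)))
        with pytest.raises(ValueError):
            sliding_feature_series(rec, ("apen",), EntropyParams(window=0.01))

    def test_unknown_estimator_rejected(self, rng):
        rec = self.make_rec(rng.standard_normal((1, 1250)))
        with pytest.raises(ValueError, match="unknown"):
            sliding_feature_series(rec, ("nope",))

    def test_wavelet_estimator_emits_ratio_features(self, rng):
        rec = self.make_rec(rng.standard_normal((1, 1250)))
        fs = sliding_feature_series(rec, ("wavelet",))
        assert fs.feature_names == ("We", "R_delta", "R_theta", "R_alpha",
                                    "R_beta", "R_gamma")
        wide = fs.wide()
        assert wide.shape == (2, 6)
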