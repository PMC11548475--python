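import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgconcord import FEATURE_NAMES, ConfigError, FeatureParams, feature_vector
from emgconcord.features import (
    amplitude_features,
    difference_features,
    statistical_features,
    threshold_count_features,
)
from feature_oracle import oracle_features

EPS = 1e-10


def as_dict(x, params=None):
    return dict(zip(FEATURE_NAMES, feature_vector(x, params)))


class TestHandComputedExamples:
    def test_constant_window(self):
        c = 0.7
        f = as_dict(np.full(10, c))
        assert f["RMS"] == pytest.approx(c)
        assert f["MAV"] == pytest.approx(c)
        assert f["IEMG"] == pytest.approx(10 * c)
        assert f["VO"] == pytest.approx(c)
        assert f["EWL"] == 0.0
        assert f["LDAMV"] == pytest.approx(math.log(EPS))
        assert f["LDASDV"] == pytest.approx(math.log(EPS))
        assert f["FZC"] == f["WA"] == f["CARD"] == 0.0
        assert f["MYOP"] == 1.0  # |0.7| >= 0.016

    def test_two_sample_window(self):
        f = as_dict(np.array([3.0, -4.0]))
        assert f["RMS"] == pytest.approx(math.sqrt(12.5))
        assert f["MAV"] == pytest.approx(3.5)
        assert f["IEMG"] == pytest.approx(7.0)

    def test_difference_features_on_hat(self):
        f = as_dict(np.array([0.0, 1.0, 0.0]))
        assert f["LDAMV"] == pytest.approx(math.log(1.0 + EPS))
        assert f["LDASDV"] == pytest.approx(math.log(1.0 + EPS))

    def test_sign_change_counts(self):
        params = FeatureParams(fzc_threshold=0.5, wa_threshold=0.5)
        f = as_dict(np.array([1.0, -1.0, 1.0, -1.0]), params)
        assert f["FZC"] == 3.0
        assert f["WA"] == 3.0

    def test_dispersion_on_1234(self):
        f = as_dict(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["SD"] == pytest.approx(math.sqrt(5.0 / 3.0))
        assert f["MAD"] == pytest.approx(1.0)
        assert f["IQR"] == pytest.approx(1.5)


class TestOracleEquivalence:
    def test_fifty_random_windows_match_loop_oracle(self):
        rng = np.random.default_rng(2024)
        params = FeatureParams()
        for _ in range(50):
            x = rng.normal(0.0, 0.3, size=16)
            got = as_dict(x, params)
            want = oracle_features(x)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(
                    want[name], rel=1e-9, abs=1e-12
                ), name

    def test_group_functions_cover_the_vector(self, rng):
        x = rng.normal(size=32)
        params = FeatureParams()
        merged = {}
        merged.update(amplitude_features(x, params))
        merged.update(difference_features(x, params))
        merged.update(threshold_count_features(x, params))
        stat, _ = statistical_features(x, params)
        merged.update(stat)
        vec = feature_vector(x, params)
        assert np.array_equal(vec, [merged[n] for n in FEATURE_NAMES])


class TestStatisticalProperties:
    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(99).standard_normal(100_000)
        f = as_dict(x)
        assert f["KURT"] == pytest.approx(3.0, abs=0.1)

    def test_kurtosis_affine_invariant(self, rng):
        x = rng.normal(size=256)
        k1 = as_dict(x)["KURT"]
        k2 = as_dict(-2.5 * x + 7.0)["KURT"]
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_zero_variance_kurt_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            f = as_dict(np.full(8, 1.0))
        assert math.isnan(f["KURT"])

    def test_cov_flagged_on_near_zero_mean(self, rng):
        x = rng.normal(size=512)
        x = x - x.mean()  # force near-zero mean
        _, flags = feature_vector(x, return_flags=True)
        assert flags.get("COV", False)


class TestScalingAndBounds:
    LINEAR = ("IEMG", "MAV", "MMAV", "MMAV2", "RMS", "VO", "SD", "MAD", "IQR")

    def test_linear_features_scale_with_amplitude(self, rng):
        x = rng.normal(size=64)
        a = 3.0
        f1, f2 = as_dict(x), as_dict(a * x)
        for name in self.LINEAR:
            assert f2[name] == pytest.approx(a * f1[name], rel=1e-9), name

    def test_fzc_invariant_under_scaling_at_zero_threshold(self, rng):
        params = FeatureParams(fzc_threshold=0.0)
        x = rng.normal(size=64)
        assert as_dict(x, params)["FZC"] == as_dict(5.0 * x, params)["FZC"]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 32))
    def test_bounds_and_finiteness(self, seed, n):
        x = np.random.default_rng(seed).normal(0, 0.5, size=n)
        f = as_dict(x)
        assert 0.0 <= f["MYOP"] <= 1.0
        assert 0.0 <= f["CARD"] <= n - 1
        assert 0.0 <= f["WA"] <= n - 1
        assert 0.0 <= f["FZC"] <= n - 1
        assert all(np.isfinite(v) for v in f.values())


class TestContract:
    def test_vector_has_22_entries_in_canonical_order(self, rng):
        vec = feature_vector(rng.normal(size=100))
        assert vec.shape == (22,)
        assert FEATURE_NAMES == (
            "FZC", "EWL", "EMAV", "ASM", "ASS", "CARD", "LDASDV", "LDAMV",
            "MYOP", "VO", "MMAV", "MMAV2", "IEMG", "RMS", "WA", "LD",
            "MAV", "MAD", "IQR", "KURT", "COV", "SD",
        )

    def test_deterministic_on_identical_windows(self, rng):
        x = rng.normal(size=64)
        assert np.array_equal(feature_vector(x), feature_vector(x.copy()))

    @pytest.mark.parametrize("bad", [np.array([1.0]), np.zeros((4, 4))])
    def test_short_or_misshapen_window_rejected(self, bad):
        with pytest.raises(ConfigError):
            feature_vector(bad)
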