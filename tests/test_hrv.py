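"""HRV feature extraction from RR-interval series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gammafs as g

from _naive import naive_derivative_moments, naive_time_domain

WORKED = g.RRSeries(np.array([800.0, 860.0, 865.0, 940.0]), "unknown", "worked")


def constant_series(value=800.0, n=80):
    return g.RRSeries(np.full(n, value), "NSR", "const")


def random_series(rng, n=70):
    base = rng.uniform(600.0, 1200.0)
    iv = rng.uniform(base - 150.0, base + 150.0, size=n)
    return g.RRSeries(iv, "unknown", "rand")


class TestQualityFilter:
    def test_clean_series_valid(self):
        v = g.quality_filter(g.RRSeries(np.linspace(600, 1100, 50)))
        assert v.valid and not v.reasons

    @pytest.mark.parametrize("bad,needle", [
        (150.0, "RR interval < 200ms"),
        (3500.0, "RR interval > 3s"),
    ])
    def test_rule_violations_flagged_with_index(self, bad, needle):
        iv = np.full(20, 800.0)
        iv[7] = bad
        v = g.quality_filter(g.RRSeries(iv))
        assert not v.valid
        assert any(needle in r and "index 7" in r for r in v.reasons)


class TestSuccessiveDerivative:
    def test_worked_orders(self):
        x = [800.0, 860.0, 865.0, 940.0]
        assert np.allclose(g.successive_derivative(x, 0), x)
        assert np.allclose(g.successive_derivative(x, 1), [60, 5, 75])
        assert np.allclose(g.successive_derivative(x, 2), [-55, 70])

    @settings(max_examples=30, derandomize=True)
    @given(n=st.integers(12, 100), order=st.integers(0, 10))
    def test_length_contract(self, n, order):
        x = np.arange(n, dtype=float)
        assert g.successive_derivative(x, order).size == n - order

    def test_errors(self):
        with pytest.raises(g.ValidationError):
            g.successive_derivative([1.0, 2.0, 3.0], 11)
        with pytest.raises(g.ValidationError):
            g.successive_derivative([1.0, 2.0, 3.0], -1)
        with pytest.raises(g.ValidationError):
            g.successive_derivative([1.0, 2.0], 2)


class TestDerivativeMoments:
    def test_constant_series_seconds_scale(self):
        m = g.derivative_moments(constant_series())
        assert m["m_0"] == pytest.approx(0.8)
        for d in range(11):
            assert m[f"sd_{d}"] == pytest.approx(0.0, abs=1e-12)
            if d > 0:
                assert m[f"m_{d}"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_trend_killed_by_second_difference(self):
        s = g.RRSeries(800.0 + 10.0 * np.arange(60))
        m = g.derivative_moments(s)
        assert m["m_1"] == pytest.approx(0.01, abs=1e-12)
        assert m["sd_1"] == pytest.approx(0.0, abs=1e-12)
        assert m["m_2"] == pytest.approx(0.0, abs=1e-12)
        assert m["sd_2"] == pytest.approx(0.0, abs=1e-12)

    def test_af_versus_nsr_short_lag_contrast(self):
        nsr = g.simulate_rr_series(g.nsr_spec(n_series=40, seed=7))
        af = g.simulate_rr_series(g.af_spec(n_series=40, seed=8))
        for key in ("sd_1", "sd_2", "sd_3"):
            m_nsr = np.mean([g.derivative_moments(s)[key] for s in nsr])
            m_af = np.mean([g.derivative_moments(s)[key] for s in af])
            assert m_af > 3.0 * m_nsr

    def test_too_short_series_rejected(self):
        with pytest.raises(g.ValidationError):
            g.derivative_moments(g.RRSeries(np.full(11, 800.0)))


class TestTimeDomainMeasures:
    def test_worked_four_beat_series(self):
        with pytest.warns(UserWarning):  # single 5-s window
            t = g.time_domain_measures(WORKED)
        assert t["pNN50"] == pytest.approx(200.0 / 3.0)
        assert t["MADRR"] == pytest.approx(60.0)
        assert t["RMSSD"] == pytest.approx(np.sqrt((60**2 + 5**2 + 75**2) / 3))

    def test_constant_series_zeros(self):
        t = g.time_domain_measures(constant_series())
        for key in ("SDNN", "SDSD", "RMSSD", "IRRR", "MADRR", "pNN50",
                    "SDANN", "SDNNidx"):
            assert t[key] == pytest.approx(0.0)

    def test_sdsd_rmssd_identity(self, rng):
        # RMSSD^2 = SDSD^2 (n-2)/(n-1) + mean(diff)^2
        for _ in range(20):
            s = random_series(rng)
            t = g.time_domain_measures(s)
            d = np.diff(s.intervals)
            expected = np.sqrt(t["SDSD"] ** 2 * (d.size - 1) / d.size
                               + d.mean() ** 2)
            assert t["RMSSD"] == pytest.approx(expected, rel=1e-12)
            assert t["RMSSD"] >= t["SDSD"] * np.sqrt((d.size - 1) / d.size)

    def test_single_window_sdann_warns_zero(self):
        s = g.RRSeries(np.array([900.0, 950.0, 880.0, 910.0]))
        with pytest.warns(UserWarning):
            t = g.time_domain_measures(s)
        assert t["SDANN"] == 0.0


class TestExtractFeatureVector:
    def test_fixed_contract(self):
        vec = g.extract_feature_vector(constant_series())
        assert list(vec.index) == list(g.FEATURE_NAMES)
        assert len(vec) == 32
        assert vec["m_0"] == pytest.approx(0.8)
        assert vec["SDNN"] == 0.0

    def test_af_series_all_sd_positive(self):
        s = g.simulate_rr_series(g.af_spec(n_series=1, seed=99))[0]
        vec = g.extract_feature_vector(s)
        assert (vec[[f"sd_{d}" for d in range(11)]] > 0).all()

    def test_invalid_series_rejected(self):
        bad = g.RRSeries(np.r_[np.full(30, 800.0), 150.0])
        with pytest.raises(g.ValidationError):
            g.extract_feature_vector(bad)


class TestInvariants:
    def test_shift_invariance_of_difference_features(self, rng):
        s = random_series(rng)
        shifted = g.RRSeries(s.intervals + 100.0)
        a, b = g.extract_feature_vector(s), g.extract_feature_vector(shifted)
        for key in ([f"sd_{d}" for d in range(1, 11)]
                    + ["SDSD", "RMSSD", "pNN50", "MADRR"]):
            assert a[key] == pytest.approx(b[key], rel=1e-9, abs=1e-12)
        assert b["m_0"] == pytest.approx(a["m_0"] + 0.1)

    def test_bounds(self, rng):
        for _ in range(20):
            vec = g.extract_feature_vector(random_series(rng))
            assert 0.0 <= vec["pNN50"] <= 100.0
            nonneg = ([f"sd_{d}" for d in range(11)]
                      + ["SDNN", "SDSD", "RMSSD", "IRRR", "MADRR",
                         "SDANN", "SDNNidx", "TINN", "HRV.index"])
            assert (vec[nonneg] >= 0).all()

    def test_agreement_with_naive_transcription(self, rng):
        for _ in range(100):
            s = random_series(rng, n=int(rng.integers(40, 90)))
            vec = g.extract_feature_vector(s)
            expected = {}
            expected.update(naive_derivative_moments(s.intervals))
            expected.update(naive_time_domain(s.intervals))
            for name in g.FEATURE_NAMES:
                assert vec[name] == pytest.approx(expected[name], abs=1e-9), name
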