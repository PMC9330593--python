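"""Rate conversion, two-site dispersion model, and amplitude extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pr10flex.constants import BACKBONE_N_CYCLES, BACKBONE_RELAX_TIME
from pr10flex.dispersion import (
    DispersionCurve,
    amplitude_delta_r2eff,
    classify_flexibility,
    compute_r2eff,
    cpmg_frequency,
    model_r2eff_closed,
    model_r2eff_limits,
    model_r2eff_numeric,
    sigma_from_repeats,
)

T = BACKBONE_RELAX_TIME


class TestComputeR2eff:
    @pytest.mark.parametrize("ratio,relax,expected", [
        (1.0, 0.030, 0.0),
        (np.exp(-1.0), 0.030, 33.3333),
        (0.5, 0.060, 11.5525),  # ln 2 / 0.06
    ])
    def test_known_values(self, ratio, relax, expected):
        assert compute_r2eff(ratio * 1e5, 1e5, relax) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_intensity_flagged_not_dropped(self):
        out = compute_r2eff(np.array([-5.0, 0.0, 1.0]), np.array([2.0, 2.0, 2.0]), 0.03)
        assert np.isnan(out[0]) and np.isnan(out[1]) and np.isfinite(out[2])

    def test_bad_reference_raises(self):
        with pytest.raises(ValueError):
            compute_r2eff(1.0, 0.0, 0.03)

    @given(rate=st.floats(0.1, 80.0), relax=st.floats(0.01, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, rate, relax):
        intensity = np.exp(-rate * relax)
        assert compute_r2eff(intensity, 1.0, relax) == pytest.approx(rate, rel=1e-9)


class TestCpmgFrequency:
    @pytest.mark.parametrize("n,relax,expected", [
        (4, 0.060, 66.7),
        (1, 0.030, 33.3),
        (120, 0.060, 2000.0),
    ])
    def test_schedule_values(self, n, relax, expected):
        assert cpmg_frequency(n, relax) == pytest.approx(expected, abs=0.05)

    def test_zero_cycles_rejected(self):
        with pytest.raises(ValueError):
            cpmg_frequency(0, 0.03)


class TestSigmaFromRepeats:
    def test_identical_repeats_hit_floor(self):
        assert sigma_from_repeats([(12.0, 12.0)], floor=0.05) == 0.05

    def test_single_pair_two_point_sd(self):
        d = 0.42
        assert sigma_from_repeats([(10.0, 10.0 + d)], floor=0.0) == pytest.approx(d / np.sqrt(2))

    def test_pooled_estimate_matches_generating_noise(self):
        rng = np.random.default_rng(3)
        sigma = 0.3
        pairs = rng.normal(15.0, sigma, size=(2000, 2))
        est = sigma_from_repeats([tuple(p) for p in pairs], floor=0.0)
        assert est == pytest.approx(sigma, rel=0.15)

    def test_no_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            sigma_from_repeats([])


class TestTwoSiteModel:
    def test_no_minor_state_is_flat(self, backbone_nus):
        out = model_r2eff_closed(1000.0, 0.0, 2.0, 15.0, 700.0, "15N",
                                 backbone_nus, relax_time=T)
        assert np.allclose(out, 15.0)

    def test_zero_shift_difference_is_flat(self, backbone_nus):
        out = model_r2eff_closed(1000.0, 0.05, 0.0, 15.0, 700.0, "15N",
                                 backbone_nus, relax_time=T)
        assert np.allclose(out, 15.0)

    def test_sign_of_shift_difference_irrelevant(self, backbone_nus):
        plus = model_r2eff_closed(800.0, 0.05, 1.5, 12.0, 600.0, "15N",
                                  backbone_nus, relax_time=T)
        minus = model_r2eff_closed(800.0, 0.05, -1.5, 12.0, 600.0, "15N",
                                   backbone_nus, relax_time=T)
        assert np.allclose(plus, minus)

    @pytest.mark.parametrize("kex", [100.0, 1000.0, 6000.0])
    @pytest.mark.parametrize("p_b", [0.005, 0.079, 0.2])
    @pytest.mark.parametrize("delta", [0.2, 2.0, 4.0])
    def test_closed_form_matches_numerical_oracle(self, kex, p_b, delta):
        """Analytic model vs explicit matrix-exponential propagation, <=1%."""
        for field in (600.0, 700.0):
            for n in BACKBONE_N_CYCLES:
                nu = n / T
                closed = model_r2eff_closed(kex, p_b, delta, 15.0, field,
                                            "15N", nu, relax_time=T)
                numeric = model_r2eff_numeric(kex, p_b, delta, 15.0, 15.0,
                                              field, "15N", n, T)
                assert closed == pytest.approx(numeric, rel=0.01)

    def test_fast_exchange_limit_population_average(self):
        """At kex >> domega the dispersion collapses onto r2_0."""
        out = model_r2eff_closed(1e6, 0.1, 1.0, 10.0, 700.0, "15N",
                                 np.array([933.3]), relax_time=T)
        assert out[0] == pytest.approx(10.0, abs=0.2)

    def test_curves_nonincreasing_in_intermediate_fast_regime(self, backbone_nus):
        """Faster pulsing refocuses more exchange broadening."""
        for kex in (500.0, 1000.0, 2000.0, 6000.0):
            for p_b in (0.013, 0.079, 0.2):
                for delta in (0.3, 1.5, 3.5):
                    for field in (600.0, 700.0):
                        c = model_r2eff_closed(kex, p_b, delta, 15.0, field,
                                               "15N", backbone_nus, relax_time=T)
                        amp = c.max() - c.min()
                        assert np.all(np.diff(c) <= 1e-6 + 5e-3 * amp)

    def test_limits_bracket_the_curve(self):
        z, inf = model_r2eff_limits(1060.0, 0.079, 2.0, 15.0, 700.0, "15N")
        curve = model_r2eff_closed(1060.0, 0.079, 2.0, 15.0, 700.0, "15N",
                                   np.array([33.3, 933.3]), relax_time=T)
        assert inf == pytest.approx(15.0)
        assert z > curve[0] > curve[1] > inf

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            model_r2eff_closed(-1.0, 0.05, 1.0, 15.0, 700.0, "15N", 100.0)
        with pytest.raises(ValueError):
            model_r2eff_closed(1000.0, 0.7, 1.0, 15.0, 700.0, "15N", 100.0)
        with pytest.raises(ValueError):
            model_r2eff_closed(1000.0, 0.05, 1.0, 15.0, 700.0, "31P", 100.0)


class TestAmplitude:
    def _curve(self, r2, sigma=0.3):
        nus = np.array(BACKBONE_N_CYCLES) / T
        return DispersionCurve(1, 700.0, nus, r2, np.full(len(nus), sigma),
                               relax_time=T)

    def test_noiseless_curve_recovers_model_amplitude(self, backbone_nus):
        model = model_r2eff_closed(1060.0, 0.079, 1.2, 15.0, 700.0, "15N",
                                   backbone_nus, relax_time=T)
        fit = amplitude_delta_r2eff(self._curve(model))
        z, inf = model_r2eff_limits(1060.0, 0.079, 1.2, 15.0, 700.0, "15N")
        assert fit.exchange_significant
        assert fit.delta_r2_eff == pytest.approx(z - inf, rel=0.02)

    def test_noiseless_flat_curve_reports_zero(self):
        fit = amplitude_delta_r2eff(self._curve(np.full(12, 15.0)))
        assert fit.converged
        assert fit.delta_r2_eff == pytest.approx(0.0, abs=1e-6)
        assert not fit.exchange_significant

    def test_flat_noisy_false_positive_rate_below_5_percent(self):
        """Noise alone must rarely be promoted above the 1 s^-1 threshold."""
        rng = np.random.default_rng(0)
        n_fp = 0
        n_rep = 150
        for _ in range(n_rep):
            r2 = 15.0 + rng.normal(0.0, 0.3, 12)
            amp = amplitude_delta_r2eff(self._curve(r2)).delta_r2_eff
            if amp is not None and abs(amp) > 1.0:
                n_fp += 1
        assert n_fp / n_rep < 0.05

    def test_too_few_points_rejected(self):
        nus = np.array([66.7, 133.3, 266.7, 400.0])
        c = DispersionCurve(1, 700.0, nus, np.full(4, 15.0), np.full(4, 0.3))
        with pytest.raises(ValueError):
            amplitude_delta_r2eff(c)


class TestClassify:
    @pytest.mark.parametrize("amp,expected", [
        (0.5, "<1"),
        (1.0, "[1,5)"),
        (7.0, "[5,10)"),
        (12.0, ">=10"),
        (None, None),
        (np.nan, None),
    ])
    def test_bins(self, amp, expected):
        assert classify_flexibility(amp) == expected
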