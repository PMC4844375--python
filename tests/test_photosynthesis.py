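"""Leaf models: forward behaviour, parameter recovery, fluorescence algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet import (
    ACiCurve,
    C3Kinetics,
    DomainError,
    FitError,
    FluorRecord,
    LightCurve,
    ValidationError,
    alternative_electron_sink,
    c4_forward,
    fit_aci,
    fit_light,
    fluorescence_params,
    fvcb_c3_forward,
    light_response,
    photorespiration,
    stomatal_limitation,
)

KIN = C3Kinetics()


class TestC3Forward:
    def test_compensation_point(self):
        assert fvcb_c3_forward(KIN.gamma_star, 80, 150, 2.5) == pytest.approx(-2.5)

    def test_rubisco_limited_hand_evaluation(self):
        # Ac = Vcmax (Ci - G*) / (Ci + Kc(1 + O/Ko)) evaluated directly
        vcmax, rd, ci = 61.0, 2.5, 300.0
        ac = vcmax * (ci - KIN.gamma_star) / (ci + KIN.km)
        a = fvcb_c3_forward(ci, vcmax, j=1e6, rd=rd)
        assert a == pytest.approx(ac - rd, rel=1e-12)

    def test_large_vcmax_limit_is_aj(self):
        ci, j, rd = 600.0, 120.0, 1.0
        aj = j * (ci - KIN.gamma_star) / (4 * ci + 8 * KIN.gamma_star)
        assert fvcb_c3_forward(ci, 1e9, j, rd) == pytest.approx(aj - rd)

    def test_monotone_nondecreasing_above_compensation(self):
        ci = np.linspace(KIN.gamma_star + 1, 1500, 200)
        a = fvcb_c3_forward(ci, 80, 150, 2.0)
        assert np.all(np.diff(a) >= -1e-12)

    def test_nonpositive_ci_rejected(self):
        with pytest.raises(DomainError):
            fvcb_c3_forward(0.0, 80, 150, 2.0)


class TestC4Forward:
    def test_saturates_at_vcmax_plateau(self):
        assert c4_forward(5000.0, 25, 55, 2.0) == pytest.approx(23.0)

    def test_saturates_at_lower_ci_than_c3(self):
        # fractional saturation at Ci = 50 vs 400 is higher for the C4 form
        c4_ratio = c4_forward(50.0, 25, 55, 0.0) / c4_forward(400.0, 25, 55, 0.0)
        c3_ratio = fvcb_c3_forward(50.0, 80, 150, 0.0) / fvcb_c3_forward(400.0, 80, 150, 0.0)
        assert c4_ratio > c3_ratio

    def test_c4_photorespiration_is_near_zero(self):
        # C4 defaults give Pr well below the C3 range
        assert photorespiration(25, 250, "C4") < 0.5
        assert photorespiration(61, 250, "C3") > 2.0


class TestLightResponse:
    def test_intercept_is_minus_rd(self):
        assert light_response(0.0, 20, 0.05, 0.7, 2.0) == pytest.approx(-2.0)

    def test_theta_zero_limit_is_rectangular_hyperbola(self):
        q = np.array([10.0, 100.0, 500.0, 1500.0])
        amax, phi, rd = 20.0, 0.05, 2.0
        rect = phi * q * amax / (phi * q + amax) - rd
        assert light_response(q, amax, phi, 0.0, rd) == pytest.approx(rect)
        # and the theta -> 0 limit of the general form converges to it
        assert light_response(q, amax, phi, 1e-12, rd) == pytest.approx(rect, rel=1e-6)


class TestFitACi:
    CI = np.array([50, 100, 150, 250, 400, 600, 800, 1100, 1500], dtype=float)

    def test_noiseless_recovery_within_tolerance(self):
        a = fvcb_c3_forward(self.CI, 80, 150, 1.5)
        fit = fit_aci(ACiCurve(self.CI, a))
        assert fit.params["vcmax"] == pytest.approx(80, rel=0.01)
        assert fit.params["j"] == pytest.approx(150, rel=0.01)
        assert fit.params["rd"] == pytest.approx(1.5, rel=0.01)

    def test_amax_co2_is_high_ci_plateau(self):
        a = fvcb_c3_forward(self.CI, 80, 150, 1.5)
        fit = fit_aci(ACiCurve(self.CI, a))
        assert fit.params["amax_co2"] == pytest.approx(
            fvcb_c3_forward(2000.0, 80, 150, 1.5), rel=0.01)

    def test_noisy_recovery_median_bias_small(self):
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(60):
            a = fvcb_c3_forward(self.CI, 80, 150, 1.5) + rng.normal(0, 0.5, len(self.CI))
            try:
                estimates.append(fit_aci(ACiCurve(self.CI, a)).params["vcmax"])
            except FitError:
                pass
        assert len(estimates) >= 50
        assert abs(np.median(estimates) - 80) / 80 < 0.05

    def test_c4_noiseless_recovery(self):
        # several sub-saturation points are needed so Vpmax and Rd separate
        ci = np.array([20, 40, 60, 100, 200, 400, 700, 1000, 1500], dtype=float)
        a = c4_forward(ci, 25, 55, 1.0)
        fit = fit_aci(ACiCurve(ci, a), pathway="C4")
        assert fit.params["vcmax"] == pytest.approx(25, rel=0.01)
        assert fit.params["vpmax"] == pytest.approx(55, rel=0.01)

    def test_flat_curve_is_an_error(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_aci(ACiCurve(self.CI, np.full(len(self.CI), 5.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            ACiCurve(np.array([100.0, 200, 300, 400]), np.array([1.0, 2, 3, 4]))


class TestFitLight:
    Q = np.array([0, 25, 50, 75, 100, 150, 200, 300, 450, 600, 800, 1200, 1800],
                 dtype=float)

    def test_noiseless_recovery_all_four_params(self):
        a = light_response(self.Q, 20, 0.05, 0.7, 2.0)
        fit = fit_light(LightCurve(self.Q, a))
        assert fit.params["amax"] == pytest.approx(20, rel=0.01)
        assert fit.params["rd"] == pytest.approx(2.0, rel=0.01)
        assert fit.params["phi"] == pytest.approx(0.05, rel=0.01)
        assert fit.params["theta"] == pytest.approx(0.7, abs=0.01)

    def test_flat_curve_is_an_error(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_light(LightCurve(self.Q, np.full(len(self.Q), 3.0)))


class TestStomatalLimitation:
    def test_arithmetic(self):
        assert stomatal_limitation(16.0, 20.0) == pytest.approx(20.0)
        assert stomatal_limitation(20.0, 20.0) == 0.0
        assert stomatal_limitation(0.0, 20.0) == pytest.approx(100.0)

    def test_supersaturation_warns_and_returns_negative(self):
        with pytest.warns(RuntimeWarning, match="negative stomatal"):
            assert stomatal_limitation(22.0, 20.0) < 0


class TestFluorescence:
    REC = dict(fo=400.0, fm=2000.0, fs=600.0, fm_prime=800.0, fo_prime=380.0,
               ppfd=1000.0)

    def test_known_values(self):
        fl = fluorescence_params(FluorRecord(**self.REC))
        assert fl.fvfm == pytest.approx(0.8)
        assert fl.df_fm == pytest.approx(0.25)
        assert fl.npq == pytest.approx(2000 / 800 - 1)
        assert fl.etr == pytest.approx(0.25 * 1000 * 0.5 * 0.84)  # = 105

    def test_npq_zero_when_fm_prime_equals_fm(self):
        rec = FluorRecord(fo=400, fm=2000, fs=600, fm_prime=2000, fo_prime=380,
                          ppfd=500)
        assert fluorescence_params(rec).npq == pytest.approx(0.0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c):
        base = fluorescence_params(FluorRecord(**self.REC))
        scaled = fluorescence_params(FluorRecord(
            fo=400 * c, fm=2000 * c, fs=600 * c, fm_prime=800 * c,
            fo_prime=380 * c, ppfd=1000.0))
        for attr in ("fvfm", "df_fm", "qp", "npq", "etr"):
            assert getattr(scaled, attr) == pytest.approx(getattr(base, attr))

    def test_invariant_violation_names_field(self):
        with pytest.raises(ValidationError, match="fm must exceed fo"):
            FluorRecord(fo=500, fm=400, fs=600, fm_prime=800, fo_prime=380,
                        ppfd=1000)


class TestAlternativeElectronSink:
    def test_arithmetic_and_linearity(self):
        assert alternative_electron_sink(0.0, 2.0, 1.5) == 0.0
        assert alternative_electron_sink(84.0, 2.0, 1.5) == pytest.approx(6.0)
        assert alternative_electron_sink(168.0, 2.0, 1.5) == pytest.approx(12.0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            alternative_electron_sink(84.0, -2.0, 1.0)
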