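"""The fitted reactivity equation, calibration, fits and classifier."""

import math

import numpy as np
import pytest

from thioreact.cdft_descriptors import ThiopheneFeatures
from thioreact.exceptions import ModelDomainError
from thioreact.reactivity_model import (
    DEFAULT_CALIBRATION,
    DEFAULT_COEFFICIENTS,
    CalibrationCoefficients,
    ModelCoefficients,
    ReactivityPrediction,
    calibrate_to_methanol,
    classify,
    f_term,
    fit_baseline_chiM,
    fit_linear_calibration,
    predict_log_krel_ideal,
    residual_sd,
)


def feat(q2=0.05, q5=0.05, s2=1.5375, s5=1.5375, S=0.5, chi=2.0, sid="f"):
    return ThiopheneFeatures(
        species_id=sid, q2=q2, q5=q5, s2_plus=s2, s5_plus=s5,
        S_global=S, chi_m=chi,
    )


class TestFTerm:
    def test_hand_evaluated_example(self):
        # chi=2, S=0.5, sigma=3.075: inner = 2*(0.5 + 10) + 0.03822/3.075
        F = f_term(feat())
        assert F == pytest.approx(1.322477, abs=1e-5)

    def test_inner_argument_of_one_gives_zero(self):
        sigma, S = 1.0, 0.25
        chi = (1.0 - DEFAULT_COEFFICIENTS.beta / sigma) / (
            S + DEFAULT_COEFFICIENTS.alpha / sigma
        )
        F = f_term(feat(s2=0.5, s5=0.5, S=S, chi=chi))
        assert abs(F) < 1e-12

    def test_monotone_decreasing_in_sigma(self):
        sigmas = np.linspace(0.1, 3.0, 40)
        Fs = [f_term(feat(s2=s / 2, s5=s / 2)) for s in sigmas]
        assert all(a > b for a, b in zip(Fs, Fs[1:]))

    def test_monotone_increasing_in_chi(self):
        chis = np.linspace(1.0, 6.0, 40)
        Fs = [f_term(feat(chi=c)) for c in chis]
        assert all(a < b for a, b in zip(Fs, Fs[1:]))

    def test_domain_errors(self):
        with pytest.raises(ModelDomainError, match="s2"):
            f_term(feat(s2=0.0, s5=0.0))
        with pytest.raises(ModelDomainError, match="argument"):
            f_term(feat(chi=-5.0, S=0.0, s2=500.0, s5=500.0))


class TestPrediction:
    def test_hand_evaluated_example(self):
        # q2+q5 = 0.1 with the F-term example above
        pred = predict_log_krel_ideal(feat())
        assert pred == pytest.approx(-46.397, abs=1e-3)

    def test_intercept_when_F_and_charges_vanish(self):
        sigma, S = 1.0, 0.25
        chi = (1.0 - DEFAULT_COEFFICIENTS.beta / sigma) / (
            S + DEFAULT_COEFFICIENTS.alpha / sigma
        )
        pred = predict_log_krel_ideal(feat(q2=0.0, q5=0.0, s2=0.5, s5=0.5, S=S, chi=chi))
        assert pred == pytest.approx(53.25, abs=1e-9)

    def test_linearity_in_total_charge(self):
        p1 = predict_log_krel_ideal(feat(q2=0.05, q5=0.05))
        p2 = predict_log_krel_ideal(feat(q2=0.10, q5=0.10))
        assert p2 - p1 == pytest.approx(8.61 * 0.1, abs=1e-12)

    def test_strictly_decreasing_in_F(self):
        # increasing chi raises F and must lower the prediction
        preds = [predict_log_krel_ideal(feat(chi=c)) for c in np.linspace(1, 6, 20)]
        assert all(a > b for a, b in zip(preds, preds[1:]))


class TestCalibration:
    def test_intercept(self):
        assert calibrate_to_methanol(0.0) == pytest.approx(8.646)

    def test_published_worked_value(self):
        assert calibrate_to_methanol(-3.39) == pytest.approx(6.866, abs=1e-3)

    def test_order_preserving(self):
        assert calibrate_to_methanol(-2.0) > calibrate_to_methanol(-5.0)

    def test_composite_slope_in_F(self):
        # d(methanol)/dF = -76.00 * 0.525 = -39.90
        chis = (2.0, 2.5)
        Fs = [f_term(feat(chi=c)) for c in chis]
        ms = [
            calibrate_to_methanol(predict_log_krel_ideal(feat(chi=c))) for c in chis
        ]
        slope = (ms[1] - ms[0]) / (Fs[1] - Fs[0])
        assert slope == pytest.approx(-39.90, abs=1e-9)


class TestFits:
    def test_calibration_fit_recovers_planted_affine(self):
        x = np.linspace(-8.0, 2.0, 25)
        y = 0.525 * x + 8.646
        cal, r2 = fit_linear_calibration(x, y)
        assert cal.slope == pytest.approx(0.525, abs=1e-10)
        assert cal.intercept == pytest.approx(8.646, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_permuted_pairing_lowers_r2(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.525 * x + 8.646 + rng.normal(0, 0.05, 40)
        _, r2 = fit_linear_calibration(x, y)
        _, r2_perm = fit_linear_calibration(x, rng.permutation(y))
        assert r2_perm < r2

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_calibration([0.0, 1.0], [0.0, 1.0])

    def test_baseline_chiM_exact_recovery(self):
        chis = np.linspace(2.0, 6.0, 30)
        feats = [feat(chi=c, sid=f"s{i}") for i, c in enumerate(chis)]
        y = [4.0 - 12.0 * math.log10(c) for c in chis]
        slope, intercept, r2 = fit_baseline_chiM(feats, y)
        assert slope == pytest.approx(-12.0, abs=1e-9)
        assert intercept == pytest.approx(4.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_excluding_planted_outlier_raises_r2(self):
        chis = np.linspace(2.0, 6.0, 30)
        feats = [feat(chi=c, sid=f"s{i}") for i, c in enumerate(chis)]
        y = [4.0 - 12.0 * math.log10(c) for c in chis]
        y[7] += 25.0  # planted outlier, species s7
        _, _, r2_all = fit_baseline_chiM(feats, y)
        _, _, r2_excl = fit_baseline_chiM(feats, y, exclude=["s7"])
        assert r2_excl > r2_all

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline_chiM([feat()], [1.0])


class TestClassifier:
    @pytest.mark.parametrize(
        "ideal,verdict",
        [(-3.39, "efficient"), (-3.0, "efficient"), (-2.9, "safer")],
    )
    def test_ideal_scale_thresholds_inclusive(self, ideal, verdict):
        pred = ReactivityPrediction("c", None, ideal)
        assert classify(pred).classification == verdict
        assert classify(pred).threshold_basis == "ideal"

    @pytest.mark.parametrize(
        "methanol,verdict", [(-4.0, "efficient"), (-3.9, "safer")]
    )
    def test_methanol_scale_when_ideal_absent(self, methanol, verdict):
        pred = ReactivityPrediction("c", None, None, methanol)
        out = classify(pred)
        assert out.classification == verdict
        assert out.threshold_basis == "methanol"

    def test_no_scale_is_an_error(self):
        with pytest.raises(ModelDomainError):
            classify(ReactivityPrediction("c", None, None, None))

    def test_disagreement_keeps_ideal_verdict_with_warning(self):
        # ideal says efficient, methanol (via the affine map) says safer
        pred = ReactivityPrediction("c", None, -3.39, calibrate_to_methanol(-3.39))
        with pytest.warns(UserWarning, match="disagrees"):
            out = classify(pred)
        assert out.classification == "efficient"
        assert out.threshold_basis == "ideal"


class TestResidualSD:
    def test_identical_sequences(self):
        assert residual_sd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_plus_minus_one(self):
        assert residual_sd([1.0, -1.0], [0.0, 0.0]) == pytest.approx(math.sqrt(2))

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=30)
        r = rng.normal(size=30)
        assert residual_sd(p + 5.0, r) == pytest.approx(residual_sd(p, r))
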