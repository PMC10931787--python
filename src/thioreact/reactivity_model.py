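"""The fitted reactivity model, its experimental calibration, and the
efficiency/safety classifier for thiophene-containing photosensitizers.

The central quantity is the base-10 logarithm of the rate constant for
singlet-oxygen [2+4] cycloaddition, relative to unmodified thiophene on
an idealized gas-phase scale:

    log10(k/kH)_ideal = 8.61 (q2 + q5) - 76.00 F + 53.25
    F = log10( chiM * (S + alpha / (s2+ + s5+)) + beta / (s2+ + s5+) )

with alpha = 30.75 (eV^2 e)^-1 and beta = 0.03822 eV^-1 e.  A fixed
affine calibration maps the ideal scale onto the experimental
methanol scale (rates relative to 2-tert-butylthiophene):

    log10(k/k2T)_Methanol = 0.525 * log10(k/kH)_ideal + 8.646

Classification: a photosensitizer whose thiophene core reacts at least
three decades slower than thiophene itself (log10(k/kH)_ideal <= -3,
or log10(k/k2T)_Methanol <= -4 when only the methanol scale is known)
is classed "efficient" (photostable enough for photodynamic action);
anything faster is "safer" (self-degrading).  Both thresholds are
inclusive on the efficient side.  The two thresholds are independent
rules on their own scales — the affine calibration does not map one
onto the other — so when both scales are available and disagree the
ideal-scale verdict wins and a warning is attached.

All logarithms here are base 10: the relative-rate scales are counted
in orders of magnitude.  Domain violations inside F (non-positive
softness sum or logarithm argument) raise; the fitted constants
presuppose valid descriptor ranges and there are no protected
operators in the fitted model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cdft_descriptors import ThiopheneFeatures
from .exceptions import ModelDomainError
from .tst_kinetics import pearson_r2

__all__ = [
    "ModelCoefficients",
    "CalibrationCoefficients",
    "ReactivityPrediction",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_CALIBRATION",
    "IDEAL_THRESHOLD",
    "METHANOL_THRESHOLD",
    "f_term",
    "predict_log_krel_ideal",
    "calibrate_to_methanol",
    "predict",
    "fit_linear_calibration",
    "fit_baseline_chiM",
    "classify",
    "residual_sd",
]

#: Efficiency threshold on the ideal (gas-phase, vs thiophene) scale.
IDEAL_THRESHOLD = -3.0
#: Efficiency threshold on the methanol (vs 2-tert-butylthiophene) scale.
METHANOL_THRESHOLD = -4.0


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients of the fitted reactivity equation.

    Defaults are the published fit; override them for refitting
    experiments (e.g. with :mod:`thioreact.symbolic_regression`).
    """

    c_charge: float = 8.61  # per e, multiplies (q2 + q5)
    c_F: float = -76.00
    c_intercept: float = 53.25
    alpha: float = 30.75  # (eV^2 e)^-1
    beta: float = 0.03822  # eV^-1 e


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Affine map from the ideal scale to the methanol scale."""

    slope: float = 0.525
    intercept: float = 8.646


DEFAULT_COEFFICIENTS = ModelCoefficients()
DEFAULT_CALIBRATION = CalibrationCoefficients()


@dataclass(frozen=True)
class ReactivityPrediction:
    """One species' predicted relative reactivity and its verdict."""

    species_id: str
    F_term: float | None
    log_krel_ideal: float | None
    log_krel_methanol: float | None = None
    classification: str | None = None  # "efficient" | "safer"
    threshold_basis: str | None = None  # "ideal" | "methanol"


def f_term(
    features: ThiopheneFeatures,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """The electronegativity/softness term F of the reactivity equation.

    F = log10( chiM (S + alpha/sigma) + beta/sigma ), sigma = s2+ + s5+.
    """
    sigma = features.s2_plus + features.s5_plus
    if sigma <= 0:
        raise ModelDomainError(
            f"species {features.species_id!r}: s2+ + s5+ = {sigma:.6g} <= 0; "
            f"the F term requires a positive local-softness sum"
        )
    inner = features.chi_m * (features.S_global + coeffs.alpha / sigma) + (
        coeffs.beta / sigma
    )
    if inner <= 0:
        raise ModelDomainError(
            f"species {features.species_id!r}: F-term logarithm argument "
            f"{inner:.6g} <= 0"
        )
    return math.log10(inner)


def predict_log_krel_ideal(
    features: ThiopheneFeatures,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """log10(k/kH) on the ideal gas-phase scale, decades vs thiophene."""
    F = f_term(features, coeffs)
    return coeffs.c_charge * (features.q2 + features.q5) + coeffs.c_F * F + (
        coeffs.c_intercept
    )


def calibrate_to_methanol(
    log_krel_ideal: float,
    cal: CalibrationCoefficients = DEFAULT_CALIBRATION,
) -> float:
    """Map an ideal-scale value onto the methanol log10(k/k2T) scale."""
    return cal.slope * log_krel_ideal + cal.intercept


def predict(
    features: ThiopheneFeatures,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
    *,
    calibrate: bool = True,
    cal: CalibrationCoefficients = DEFAULT_CALIBRATION,
) -> ReactivityPrediction:
    """Full prediction for one species, classified."""
    F = f_term(features, coeffs)
    ideal = coeffs.c_charge * (features.q2 + features.q5) + coeffs.c_F * F + (
        coeffs.c_intercept
    )
    methanol = calibrate_to_methanol(ideal, cal) if calibrate else None
    pred = ReactivityPrediction(
        species_id=features.species_id,
        F_term=F,
        log_krel_ideal=ideal,
        log_krel_methanol=methanol,
    )
    return classify(pred)


def classify(pred: ReactivityPrediction) -> ReactivityPrediction:
    """Apply the efficiency/safety thresholds to a prediction.

    The ideal-scale rule (<= -3 decades: efficient) takes precedence;
    the methanol rule (<= -4) applies when only that scale is present.
    When both scales are present and disagree, the ideal verdict is kept
    and a warning is raised.
    """
    ideal = pred.log_krel_ideal
    methanol = pred.log_krel_methanol
    if ideal is None and methanol is None:
        raise ModelDomainError(
            f"species {pred.species_id!r}: no reactivity scale available to classify"
        )
    if ideal is not None:
        verdict = "efficient" if ideal <= IDEAL_THRESHOLD else "safer"
        basis = "ideal"
        if methanol is not None:
            methanol_verdict = (
                "efficient" if methanol <= METHANOL_THRESHOLD else "safer"
            )
            if methanol_verdict != verdict:
                warnings.warn(
                    f"species {pred.species_id!r}: ideal-scale verdict "
                    f"{verdict!r} disagrees with methanol-scale verdict "
                    f"{methanol_verdict!r}; keeping the ideal-scale verdict",
                    stacklevel=2,
                )
    else:
        verdict = "efficient" if methanol <= METHANOL_THRESHOLD else "safer"
        basis = "methanol"
    return ReactivityPrediction(
        species_id=pred.species_id,
        F_term=pred.F_term,
        log_krel_ideal=ideal,
        log_krel_methanol=methanol,
        classification=verdict,
        threshold_basis=basis,
    )


def fit_linear_calibration(
    ideal: Sequence[float], observed: Sequence[float]
) -> tuple[CalibrationCoefficients, float]:
    """Ordinary-least-squares affine adjustment of the ideal scale to
    observed (experimental) log relative rates.

    Returns the fitted coefficients and the r^2 between the two scales.
    """
    x = np.asarray(ideal, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ideal and observed must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: ideal values are constant")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean())) / float(xc @ xc)
    intercept = float(y.mean() - slope * x.mean())
    r2 = pearson_r2(x, y)
    return CalibrationCoefficients(slope=slope, intercept=intercept), r2


def fit_baseline_chiM(
    features_list: Sequence[ThiopheneFeatures],
    log_krel_list: Sequence[float],
    exclude: Sequence[str] = (),
) -> tuple[float, float, float]:
    """Baseline one-descriptor model: OLS of log-relative-rate on
    log10(chiM), with an optional exclusion list of species ids for
    outlier handling.

    Returns (slope, intercept, r2).
    """
    if len(features_list) != len(log_krel_list):
        raise ValueError("features and responses differ in length")
    excluded = set(exclude)
    xs, ys = [], []
    for feat, y in zip(features_list, log_krel_list):
        if feat.species_id in excluded:
            continue
        if feat.chi_m <= 0:
            raise ModelDomainError(
                f"species {feat.species_id!r}: chiM = {feat.chi_m:.6g} <= 0, "
                f"log10(chiM) undefined"
            )
        xs.append(math.log10(feat.chi_m))
        ys.append(y)
    if len(xs) < 3:
        raise ValueError(f"need at least 3 included species, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: log10(chiM) values are constant")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean())) / float(xc @ xc)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, pearson_r2(x, y)


def residual_sd(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """Sample standard deviation of (predicted - reference), decades."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("predicted and reference must be 1-D of equal length")
    if p.size < 2:
        raise ValueError("need at least 2 points for a sample SD")
    return float(np.std(p - r, ddof=1))
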