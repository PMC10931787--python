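"""Eyring transition-state-theory kinetics and benchmark statistics.

The absolute rate constant follows the Eyring equation

    k = gamma * (kB*T/h) * exp(-dG_act / (R*T))

with the transmission coefficient gamma = 1 by default.  Relative rates
are reported as base-10 log ratios ("decades"), where the kB*T/h
prefactor and gamma cancel, so standard-state subtleties of the
bimolecular cycloaddition do not affect them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (
    BOLTZMANN_J_PER_K,
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT_J_PER_MOL_K,
    KCAL_TO_KJ,
    PLANCK_J_S,
)

__all__ = [
    "RateRecord",
    "eyring_rate",
    "log10_relative_rate",
    "pearson_r2",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class RateRecord:
    """A computed rate constant and its inputs (effective first-order)."""

    species_id: str
    delta_G_activation: float  # kJ/mol
    temperature: float  # K
    transmission_coeff: float
    k: float  # 1/s

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.transmission_coeff <= 0:
            raise ValueError("transmission coefficient must be positive")
        if self.k <= 0:
            raise ValueError("rate constant must be positive")


def eyring_rate(
    delta_G_activation: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    transmission_coeff: float = 1.0,
    *,
    kcal: bool = False,
) -> float:
    """Eyring rate constant, 1/s.

    ``delta_G_activation`` is the Gibbs free energy of activation in
    kJ/mol (kcal/mol only via the explicit ``kcal`` flag).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    dg = delta_G_activation * KCAL_TO_KJ if kcal else delta_G_activation
    prefactor = BOLTZMANN_J_PER_K * temperature / PLANCK_J_S
    return transmission_coeff * prefactor * math.exp(
        -dg * 1000.0 / (GAS_CONSTANT_J_PER_MOL_K * temperature)
    )


def log10_relative_rate(
    delta_G: float,
    delta_G_ref: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """log10(k / k_ref) in decades, from activation free energies (kJ/mol).

    Equals -(dG - dG_ref) / (R*T*ln10); the Eyring prefactor and the
    transmission coefficient cancel exactly.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -(delta_G - delta_G_ref) * 1000.0 / (
        GAS_CONSTANT_J_PER_MOL_K * temperature * _LN10
    )


def pearson_r2(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Square of the sample Pearson correlation coefficient, in [0, 1].

    Raises ``ValueError`` for unequal lengths, fewer than three points,
    or a constant sequence (undefined correlation).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for a constant sequence")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    return min(r * r, 1.0)
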