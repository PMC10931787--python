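"""Physical constants used across the package.

All unit conversions are explicit; nothing in the package converts
energies implicitly.
"""

from scipy import constants as _sc

#: Hartree -> electronvolt (CODATA 2018).
HARTREE_TO_EV: float = 27.211386245988

#: Boltzmann constant, J/K (exact, SI 2019).
BOLTZMANN_J_PER_K: float = _sc.k

#: Planck constant, J*s (exact, SI 2019).
PLANCK_J_S: float = _sc.h

#: Molar gas constant, J/(mol*K) (exact, SI 2019).
GAS_CONSTANT_J_PER_MOL_K: float = _sc.R

#: Thermochemical calorie, J (for kcal/mol inputs).
KCAL_TO_KJ: float = 4.184

#: Default temperature for transition-state-theory kinetics, K.
DEFAULT_TEMPERATURE_K: float = 298.15


def hartree_to_ev(x: float) -> float:
    """Convert an energy from hartree to eV (exact multiplication)."""
    return x * HARTREE_TO_EV
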