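"""Deterministic synthetic generators for every input the tool consumes.

Three kinds of fixtures:

* species triplets (:func:`generate_species`) with energies placed so
  that VIP/VEA land in requested ranges and per-state charges that sum
  *exactly* to the molecular charge (0 / +1 / -1 e for N / N-1 / N+1);
* ORCA-style plain-text single points (:func:`write_orca_fixture`)
  in the dialect :mod:`thioreact.qc_state_io` parses;
* descriptor/response tables (:func:`generate_regression_dataset`)
  with a planted formula plus optional Gaussian noise, for exercising
  the symbolic-regression engine and the fitted model.

Charges are drawn on a dyadic grid (multiples of 2^-16 e) and the
electron gained/lost between states is distributed as exact grid
fractions, so condensed Fukui functions sum to exactly 1 e in double
arithmetic — normalization is a sharp test, not an approximate one.
These are statistical stand-ins chosen to exercise the pipeline over
plausible descriptor ranges; they make no attempt to mimic real
thiophene electronic structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cdft_descriptors import ThiopheneFeatures
from .constants import HARTREE_TO_EV
from .exceptions import ValidationError
from .qc_state_io import ElectronicState, SpeciesRecord
from .reactivity_model import DEFAULT_COEFFICIENTS, predict_log_krel_ideal
from .symbolic_regression import RegressionDataset

__all__ = [
    "FixtureSpec",
    "generate_species",
    "write_orca_fixture",
    "generate_regression_dataset",
]

#: Charge grid: all synthetic charges are multiples of 2^-16 e.
_GRID = 1 << 16

#: Default descriptor ranges for regression tables (units as in the model).
DEFAULT_FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "chiM": (2.0, 6.0),  # eV
    "S": (0.1, 0.6),  # eV^-1
    "sigma": (0.05, 1.5),  # eV^-1 e, split into s2plus + s5plus
    "q": (-0.15, 0.15),  # e
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture draw.

    ``seed`` is mandatory; every generated artifact is a pure function
    of the spec.  VIP/VEA ranges must not overlap (lower VIP bound above
    upper VEA bound) so that every species has a positive hardness.
    """

    seed: int
    n_species: int = 90
    atom_count_range: tuple[int, int] = (9, 24)
    vip_range: tuple[float, float] = (6.0, 10.0)  # eV
    vea_range: tuple[float, float] = (-0.5, 3.0)  # eV
    charge_scale: float = 0.15  # max |q_k(N)|, e
    with_gibbs: bool = False
    gibbs_range: tuple[float, float] = (60.0, 140.0)  # kJ/mol
    planted: str | Callable[[pd.DataFrame], np.ndarray] = "eq1"
    noise_sd: float = 0.0
    feature_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_RANGES)
    )

    def __post_init__(self) -> None:
        for name in ("atom_count_range", "vip_range", "vea_range", "gibbs_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} is empty: ({lo}, {hi})")
        if self.atom_count_range[0] < 5:
            raise ValidationError("atom_count_range must start at >= 5 atoms")
        if self.vip_range[0] <= self.vea_range[1]:
            raise ValidationError(
                "infeasible ranges: min VIP must exceed max VEA so that "
                "hardness stays positive"
            )
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _grid_charges_zero_sum(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Integer grid charges with exact zero sum (units of 2^-16 e)."""
    m = max(1, int(round(scale * _GRID)))
    q = rng.integers(-m, m + 1, size=n)
    total = int(q.sum())
    share, rem = divmod(total, n)
    q = q - share
    q[:rem] -= 1
    assert int(q.sum()) == 0
    return q


def _grid_unit_partition(rng: np.random.Generator, n: int, bump: int) -> np.ndarray:
    """Non-negative grid fractions summing exactly to one electron.

    ``bump`` is the atom index receiving the rounding remainder, which
    also guarantees it a strictly positive share.
    """
    a = rng.integers(1, 1000, size=n)
    b = (a * _GRID) // int(a.sum())
    rem = _GRID - int(b.sum())
    b[bump] += rem
    assert int(b.sum()) == _GRID and (b >= 0).all()
    return b


_METHOD_LABEL = "wB97X-D3/def2-TZVP (synthetic)"


def generate_species(spec: FixtureSpec) -> list[SpeciesRecord]:
    """Deterministically generate ``spec.n_species`` valid triplets.

    Atom 0 plays the thiophene sulfur, atoms 1-4 the ring carbons; the
    alpha carbons (positions 2 and 5 of the ring) are atoms 1 and 4.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SpeciesRecord] = []
    for i in range(spec.n_species):
        n_atoms = int(rng.integers(spec.atom_count_range[0], spec.atom_count_range[1] + 1))
        vip = float(rng.uniform(*spec.vip_range))
        vea = float(rng.uniform(*spec.vea_range))
        e_n = -(150.0 + 2.0 * i + float(rng.uniform(0.0, 1.0)))  # hartree
        e_nm1 = e_n + vip / HARTREE_TO_EV
        e_np1 = e_n - vea / HARTREE_TO_EV

        q_n = _grid_charges_zero_sum(rng, n_atoms, spec.charge_scale)
        f_plus = _grid_unit_partition(rng, n_atoms, bump=1)
        f_minus = _grid_unit_partition(rng, n_atoms, bump=4)
        q_np1 = q_n - f_plus  # anion: one extra electron, total -1 e
        q_nm1 = q_n + f_minus  # cation: one electron removed, total +1 e

        def _state(label: str, energy: float, grid_q: np.ndarray) -> ElectronicState:
            return ElectronicState(
                electron_count_label=label,
                total_energy=energy,
                charges=tuple(float(v) / _GRID for v in grid_q),
                energy_unit="hartree",
                method_label=_METHOD_LABEL,
                charge_scheme_label="Hirshfeld",
            )

        records.append(
            SpeciesRecord(
                species_id=f"syn-{i + 1:03d}",
                states=(
                    _state("N", e_n, q_n),
                    _state("N-1", e_nm1, q_nm1),
                    _state("N+1", e_np1, q_np1),
                ),
                alpha_atom_indices=(1, 4),
                gibbs_activation=(
                    float(rng.uniform(*spec.gibbs_range)) if spec.with_gibbs else None
                ),
                notes="synthetic fixture",
            )
        )
    return records


def write_orca_fixture(
    state: ElectronicState,
    path: str | Path,
    elements: Sequence[str] | None = None,
) -> None:
    """Write one state as an ORCA-style plain-text single point.

    Emits the dialect :func:`thioreact.qc_state_io.parse_orca_output`
    reads: a ``FINAL SINGLE POINT ENERGY`` line and a ``HIRSHFELD
    ANALYSIS`` table.  Numbers are printed with full ``repr`` precision
    so that parse(write(state)) reproduces energy and charges exactly.
    """
    n = state.atom_count
    if elements is None:
        elements = ["S"] + ["C"] * (n - 1)
    if len(elements) != n:
        raise ValidationError(
            f"elements length {len(elements)} != atom count {n}"
        )
    if state.energy_unit != "hartree":
        raise ValidationError("ORCA fixtures store energies in hartree")
    lines = [
        "*** synthetic single point ***",
        f"# state: {state.electron_count_label}   method: {state.method_label}",
        "",
        "-------------------------   --------------------",
        f"FINAL SINGLE POINT ENERGY      {state.total_energy!r}",
        "-------------------------   --------------------",
        "",
        "------------------",
        "HIRSHFELD ANALYSIS",
        "------------------",
        "",
        "  ATOM     CHARGE      SPIN",
    ]
    for i, (el, q) in enumerate(zip(elements, state.charges)):
        lines.append(f"  {i:>4d} {el:<2s}   {q!r}   0.000000")
    total = math.fsum(state.charges)
    lines += [f"  TOTAL   {total!r}   0.000000", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Regression tables with planted formulas
# ---------------------------------------------------------------------------


def _eq1_features(rng: np.random.Generator, n: int, ranges: dict) -> pd.DataFrame:
    chi = rng.uniform(*ranges["chiM"], size=n)
    s_glob = rng.uniform(*ranges["S"], size=n)
    sigma = rng.uniform(*ranges["sigma"], size=n)
    share = rng.uniform(0.2, 0.8, size=n)  # s2+ fraction of sigma
    q2 = rng.uniform(*ranges["q"], size=n)
    q5 = rng.uniform(*ranges["q"], size=n)
    return pd.DataFrame(
        {
            "q2": q2,
            "q5": q5,
            "s2plus": sigma * share,
            "s5plus": sigma * (1.0 - share),
            "S": s_glob,
            "chiM": chi,
        }
    )


def eq1_response(features: pd.DataFrame) -> np.ndarray:
    """Evaluate the fitted reactivity equation row-wise on a feature table."""
    out = np.empty(len(features))
    for i, row in enumerate(features.itertuples(index=False)):
        feat = ThiopheneFeatures(
            species_id=f"row-{i}",
            q2=row.q2,
            q5=row.q5,
            s2_plus=row.s2plus,
            s5_plus=row.s5plus,
            S_global=row.S,
            chi_m=row.chiM,
        )
        out[i] = predict_log_krel_ideal(feat, DEFAULT_COEFFICIENTS)
    return out


#: Constants of the planted "linear" and "fshape" formulas.
LINEAR_COEFFS = (3.2, -1.5)
FSHAPE_COEFFS = (0.5, 0.2)


def generate_regression_dataset(spec: FixtureSpec) -> RegressionDataset:
    """Descriptor/response table with a planted formula.

    Planted models:

    * ``"eq1"`` — features in reactivity-model ranges, response from the
      fitted equation with the published constants;
    * ``"linear"`` — two standard-normal features, response
      ``3.2*x0 - 1.5*x1``;
    * ``"fshape"`` — response ``log10(0.5*x0 + 0.2/x1)`` with x0 in the
      electronegativity range and x1 in the local-softness-sum range;
    * a callable — receives the eq1-style feature table, returns the
      response.

    Gaussian noise with SD ``spec.noise_sd`` is added to the response.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    ranges = {**DEFAULT_FEATURE_RANGES, **spec.feature_ranges}
    planted = spec.planted
    if callable(planted):
        X = _eq1_features(rng, n, ranges)
        y = np.asarray(planted(X), dtype=float)
        desc = "custom planted model"
    elif planted == "eq1":
        X = _eq1_features(rng, n, ranges)
        y = eq1_response(X)
        desc = "planted fitted reactivity equation"
    elif planted == "linear":
        X = pd.DataFrame(
            {"x0": rng.standard_normal(n), "x1": rng.standard_normal(n)}
        )
        a, b = LINEAR_COEFFS
        y = a * X["x0"].to_numpy() + b * X["x1"].to_numpy()
        desc = f"planted linear model y = {a}*x0 + {b}*x1"
    elif planted == "fshape":
        X = pd.DataFrame(
            {
                "x0": rng.uniform(*ranges["chiM"], size=n),
                "x1": rng.uniform(*ranges["sigma"], size=n),
            }
        )
        c1, c2 = FSHAPE_COEFFS
        y = np.log10(c1 * X["x0"].to_numpy() + c2 / X["x1"].to_numpy())
        desc = f"planted F-shaped model y = log10({c1}*x0 + {c2}/x1)"
    else:
        raise ValidationError(f"unknown planted model {planted!r}")
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    return RegressionDataset(features=X, response=y, description=desc)
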