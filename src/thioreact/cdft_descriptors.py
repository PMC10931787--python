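"""Conceptual-DFT reactivity descriptors by finite differences.

Global descriptors (ionization potential, electron affinity, Mulliken
electronegativity, chemical potential, hardness, softness,
electrophilicity) are computed from the total energies of the N, N-1
and N+1 electron states at the N-electron geometry; condensed local
descriptors (Fukui functions, local softness) from the per-atom
Hirshfeld charges of the same triplet.

Definitions (all energies in eV, charges in e):

    VIP  = E(N-1) - E(N)            vertical ionization potential
    VEA  = E(N) - E(N+1)            vertical electron affinity
    chiM = (VIP + VEA) / 2          Mulliken electronegativity
    mu   = -chiM                    chemical potential
    eta  = VIP - VEA                hardness (fundamental gap)
    S    = 1 / eta                  global softness (eta > 0)
    omega = mu^2 / (2 eta)          electrophilicity index (eta > 0)

    f+_k = q_k(N) - q_k(N+1)        condensed Fukui, nucleophilic attack
    f-_k = q_k(N-1) - q_k(N)        condensed Fukui, electrophilic attack
    f0_k = (f+_k + f-_k) / 2
    s+_k = S * f+_k                 condensed local softness

Only the vertical finite-difference definitions are implemented; there
is no orbital-energy (Koopmans) fallback.  A negative VEA (unbound
anion) is returned as-is, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DescriptorDomainError, ValidationError
from .qc_state_io import SpeciesRecord

__all__ = [
    "GlobalCDFT",
    "CondensedLocal",
    "ThiopheneFeatures",
    "vertical_ionization_potential",
    "vertical_electron_affinity",
    "global_descriptors",
    "condensed_local",
    "nucleophilicity_index",
    "thiophene_features",
    "descriptor_table",
]


@dataclass(frozen=True)
class GlobalCDFT:
    """Global conceptual-DFT descriptors of one species (eV scale).

    ``s_global`` and ``omega`` are ``None`` when the fundamental gap is
    non-positive (softness undefined).
    """

    vip: float
    vea: float
    chi_m: float
    mu: float
    eta: float
    s_global: float | None
    omega: float | None
    nucleophilicity: float | None = None


@dataclass(frozen=True)
class CondensedLocal:
    """Per-atom condensed Fukui functions and local softness.

    Arrays are indexed by atom, in input order.  ``s_plus``/``s_minus``
    are ``None`` when global softness is undefined.
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    f_zero: np.ndarray
    s_plus: np.ndarray | None
    s_minus: np.ndarray | None


@dataclass(frozen=True)
class ThiopheneFeatures:
    """The six inputs of the reactivity model, for one species.

    q2/q5: neutral-state Hirshfeld charges at the alpha carbons (e);
    s2_plus/s5_plus: condensed local softness for nucleophilic attack
    at the same atoms (eV^-1 e); S_global: global softness (eV^-1);
    chi_m: Mulliken electronegativity (eV).
    """

    species_id: str
    q2: float
    q5: float
    s2_plus: float
    s5_plus: float
    S_global: float
    chi_m: float


def vertical_ionization_potential(record: SpeciesRecord) -> float:
    """VIP = E(N-1) - E(N), in eV."""
    return record.state("N-1").energy_in_ev() - record.state("N").energy_in_ev()


def vertical_electron_affinity(record: SpeciesRecord) -> float:
    """VEA = E(N) - E(N+1), in eV.  May be negative (unbound anion)."""
    return record.state("N").energy_in_ev() - record.state("N+1").energy_in_ev()


def global_descriptors(record: SpeciesRecord) -> GlobalCDFT:
    """All global descriptors of one species.

    Softness and electrophilicity are left undefined (``None``) when the
    hardness is non-positive; every other field is always computed.
    """
    vip = vertical_ionization_potential(record)
    vea = vertical_electron_affinity(record)
    chi_m = (vip + vea) / 2.0
    mu = -chi_m
    eta = vip - vea
    if eta > 0:
        s_global = 1.0 / eta
        omega = mu * mu / (2.0 * eta)
    else:
        s_global = None
        omega = None
    return GlobalCDFT(
        vip=vip, vea=vea, chi_m=chi_m, mu=mu, eta=eta, s_global=s_global, omega=omega
    )


def condensed_local(
    record: SpeciesRecord, glob: GlobalCDFT | None = None
) -> CondensedLocal:
    """Condensed Fukui functions and local softness for every atom."""
    if glob is None:
        glob = global_descriptors(record)
    q_n = np.asarray(record.state("N").charges, dtype=float)
    q_np1 = np.asarray(record.state("N+1").charges, dtype=float)
    q_nm1 = np.asarray(record.state("N-1").charges, dtype=float)
    if not (len(q_n) == len(q_np1) == len(q_nm1)):
        raise ValidationError(
            f"species {record.species_id!r}: charge sequences differ in length"
        )
    f_plus = q_n - q_np1
    f_minus = q_nm1 - q_n
    f_zero = (f_plus + f_minus) / 2.0
    if glob.s_global is not None:
        s_plus = glob.s_global * f_plus
        s_minus = glob.s_global * f_minus
    else:
        s_plus = None
        s_minus = None
    return CondensedLocal(
        f_plus=f_plus, f_minus=f_minus, f_zero=f_zero, s_plus=s_plus, s_minus=s_minus
    )


def nucleophilicity_index(record: SpeciesRecord, reference_energy: float) -> float:
    """Relative nucleophilicity, -VIP - reference_energy (eV).

    The reference is the HOMO-proxy energy of a caller-chosen reference
    electrophile (conventionally tetracyanoethylene); there is no
    default, because the index is meaningful only relative to it.
    """
    return -vertical_ionization_potential(record) - reference_energy


def thiophene_features(record: SpeciesRecord) -> ThiopheneFeatures:
    """Bundle the six reactivity-model inputs for one species.

    Pure bookkeeping: neutral-state charges at the alpha carbons plus the
    global and condensed-local softness values computed above.
    """
    glob = global_descriptors(record)
    if glob.s_global is None:
        raise DescriptorDomainError(
            f"species {record.species_id!r}: global softness undefined "
            f"(hardness {glob.eta:.6g} eV <= 0)"
        )
    local = condensed_local(record, glob)
    i2, i5 = record.alpha_atom_indices
    n_atoms = record.atom_count
    for i in (i2, i5):
        if not 0 <= i < n_atoms:
            raise ValidationError(
                f"species {record.species_id!r}: alpha atom index {i} out of range"
            )
    q_n = record.state("N").charges
    assert local.s_plus is not None
    return ThiopheneFeatures(
        species_id=record.species_id,
        q2=q_n[i2],
        q5=q_n[i5],
        s2_plus=float(local.s_plus[i2]),
        s5_plus=float(local.s_plus[i5]),
        S_global=glob.s_global,
        chi_m=glob.chi_m,
    )


def descriptor_table(records) -> "pd.DataFrame":
    """Descriptor export: one row per species.

    Columns: VIP, VEA, chiM, mu, eta (eV); S, s2plus, s5plus (eV^-1 [e]);
    omega (eV); q2, q5, f2plus, f5plus (e).
    """
    import pandas as pd

    rows = []
    for r in records:
        glob = global_descriptors(r)
        local = condensed_local(r, glob)
        i2, i5 = r.alpha_atom_indices
        q_n = r.state("N").charges
        rows.append(
            {
                "species_id": r.species_id,
                "VIP": glob.vip,
                "VEA": glob.vea,
                "chiM": glob.chi_m,
                "mu": glob.mu,
                "eta": glob.eta,
                "S": glob.s_global,
                "omega": glob.omega,
                "q2": q_n[i2],
                "q5": q_n[i5],
                "f2plus": float(local.f_plus[i2]),
                "f5plus": float(local.f_plus[i5]),
                "s2plus": float(local.s_plus[i2]) if local.s_plus is not None else None,
                "s5plus": float(local.s_plus[i5]) if local.s_plus is not None else None,
            }
        )
    return pd.DataFrame(rows)
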