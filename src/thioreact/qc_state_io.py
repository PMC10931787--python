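"""Read and write species electronic-state data.

A *species* is one molecule for which single-point energies and per-atom
Hirshfeld charges are available in three electron states: the neutral
N-electron ground state and the vertical N-1 (cation) and N+1 (anion)
states, all at the N-electron geometry.  This module defines the
in-memory containers (:class:`ElectronicState`, :class:`SpeciesRecord`),
a parser for ORCA-style plain-text single-point output, and a canonical
JSON document format that round-trips bit-identically.

Atom indices are 0-based throughout, matching ORCA's printing.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .exceptions import ParseError, ValidationError

__all__ = [
    "ElectronicState",
    "SpeciesRecord",
    "STATE_LABELS",
    "ENERGY_UNITS",
    "parse_orca_output",
    "read_species_table",
    "write_species_table",
    "write_species_csv",
]

#: The three vertical electron-count states of a species.
STATE_LABELS = ("N", "N-1", "N+1")

#: Recognised energy unit tags.  Conversion is always explicit.
ENERGY_UNITS = ("hartree", "eV")

FORMAT_VERSION = "1"


@dataclass(frozen=True)
class ElectronicState:
    """A single electron-count state: total energy plus per-atom charges.

    Parameters
    ----------
    electron_count_label:
        One of ``"N"``, ``"N-1"``, ``"N+1"``.
    total_energy:
        Total electronic energy in the unit given by ``energy_unit``.
    charges:
        Per-atom Hirshfeld charges (electron units), in file order.
    """

    electron_count_label: str
    total_energy: float
    charges: tuple[float, ...]
    energy_unit: str = "hartree"
    method_label: str = ""
    charge_scheme_label: str = "Hirshfeld"

    def __post_init__(self) -> None:
        if self.electron_count_label not in STATE_LABELS:
            raise ValidationError(
                f"electron_count_label must be one of {STATE_LABELS}, "
                f"got {self.electron_count_label!r}"
            )
        if self.energy_unit not in ENERGY_UNITS:
            raise ValidationError(
                f"energy_unit must be one of {ENERGY_UNITS}, got {self.energy_unit!r}"
            )
        object.__setattr__(self, "charges", tuple(float(q) for q in self.charges))

    @property
    def atom_count(self) -> int:
        return len(self.charges)

    def energy_in_ev(self) -> float:
        """Total energy converted to eV (explicit conversion point)."""
        from .constants import hartree_to_ev

        if self.energy_unit == "eV":
            return self.total_energy
        return hartree_to_ev(self.total_energy)


@dataclass(frozen=True)
class SpeciesRecord:
    """The N / N-1 / N+1 state triplet of one species.

    ``alpha_atom_indices`` are the 0-based positions of the two ring
    carbons alpha to sulfur (the thiophene 2- and 5-carbons), the sites
    attacked by singlet oxygen in the [2+4] cycloaddition.

    ``at_n_geometry`` asserts that all three states were computed at the
    geometry optimised for the N-electron state; this is metadata the
    caller vouches for, it cannot be checked numerically.
    """

    species_id: str
    states: tuple[ElectronicState, ElectronicState, ElectronicState]
    alpha_atom_indices: tuple[int, int]
    gibbs_activation: float | None = None  # kJ/mol, optional, for TST
    notes: str = ""
    at_n_geometry: bool = True

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        object.__setattr__(
            self, "alpha_atom_indices", tuple(int(i) for i in self.alpha_atom_indices)
        )
        labels = [s.electron_count_label for s in states]
        if sorted(labels) != sorted(STATE_LABELS):
            raise ValidationError(
                f"species {self.species_id!r}: need exactly the states "
                f"{STATE_LABELS}, got {labels}"
            )
        n_atoms = {s.atom_count for s in states}
        if len(n_atoms) != 1:
            raise ValidationError(
                f"species {self.species_id!r}: charge sequences differ in length "
                f"across states: {sorted(n_atoms)}"
            )
        i2, i5 = self.alpha_atom_indices
        if i2 == i5:
            raise ValidationError(
                f"species {self.species_id!r}: alpha_atom_indices must be distinct"
            )
        count = states[0].atom_count
        for i in (i2, i5):
            if not 0 <= i < count:
                raise ValidationError(
                    f"species {self.species_id!r}: alpha atom index {i} out of "
                    f"range for {count} atoms"
                )

    def state(self, label: str) -> ElectronicState:
        """Return the state with the given electron-count label."""
        for s in self.states:
            if s.electron_count_label == label:
                return s
        raise ValidationError(f"species {self.species_id!r}: missing state {label!r}")

    @property
    def atom_count(self) -> int:
        return self.states[0].atom_count


# ---------------------------------------------------------------------------
# ORCA-style plain-text parsing
# ---------------------------------------------------------------------------

_ENERGY_TOKEN = "FINAL SINGLE POINT ENERGY"
_HIRSHFELD_TOKEN = "HIRSHFELD ANALYSIS"
_FLOAT_RE = r"[-+]?\d+\.\d+(?:[eE][-+]?\d+)?"
_CHARGE_ROW_RE = re.compile(
    rf"^\s*(\d+)\s+([A-Za-z]{{1,3}})\s+({_FLOAT_RE})(?:\s+{_FLOAT_RE})?\s*$"
)


def parse_orca_output(
    text: str,
    electron_count_label: str,
    method_label: str = "",
) -> ElectronicState:
    """Parse one ORCA-style single-point output into an :class:`ElectronicState`.

    The dialect: the total energy is taken from the unique line containing
    the literal token ``FINAL SINGLE POINT ENERGY`` (last number on the
    line, hartree); charges from the unique ``HIRSHFELD ANALYSIS`` table,
    whose rows are ``index  element  charge [spin]``.  Duplicate marker
    lines are an error rather than last-wins: silent misparses are worse
    than failures.
    """
    lines = text.splitlines()

    energy_lines = [
        (i, ln) for i, ln in enumerate(lines) if _ENERGY_TOKEN in ln
    ]
    if not energy_lines:
        raise ParseError(f"no line containing {_ENERGY_TOKEN!r} found")
    if len(energy_lines) > 1:
        raise ParseError(
            f"ambiguous input: {len(energy_lines)} lines contain "
            f"{_ENERGY_TOKEN!r} (lines {[i + 1 for i, _ in energy_lines]})"
        )
    _, energy_line = energy_lines[0]
    numbers = re.findall(_FLOAT_RE, energy_line)
    if not numbers:
        raise ParseError(f"no energy value on the {_ENERGY_TOKEN!r} line")
    energy = float(numbers[-1])

    block_starts = [i for i, ln in enumerate(lines) if _HIRSHFELD_TOKEN in ln]
    if not block_starts:
        raise ParseError(f"no {_HIRSHFELD_TOKEN!r} block found")
    if len(block_starts) > 1:
        raise ParseError(
            f"ambiguous input: {len(block_starts)} {_HIRSHFELD_TOKEN!r} blocks"
        )
    start = block_starts[0]

    # Find the ATOM header, then read charge rows until TOTAL or blank.
    header = None
    for j in range(start + 1, len(lines)):
        if re.match(r"^\s*ATOM\b", lines[j]):
            header = j
            break
    if header is None:
        raise ParseError(
            f"{_HIRSHFELD_TOKEN!r} block at line {start + 1} has no ATOM header"
        )

    charges: list[float] = []
    for j in range(header + 1, len(lines)):
        ln = lines[j]
        if not ln.strip() or ln.lstrip().startswith("TOTAL"):
            break
        m = _CHARGE_ROW_RE.match(ln)
        if m is None:
            raise ParseError(f"malformed Hirshfeld charge row at line {j + 1}: {ln!r}")
        idx = int(m.group(1))
        if idx != len(charges):
            raise ParseError(
                f"non-consecutive atom index {idx} at line {j + 1} "
                f"(expected {len(charges)})"
            )
        charges.append(float(m.group(3)))
    if not charges:
        raise ParseError(f"empty Hirshfeld charge table after line {header + 1}")

    return ElectronicState(
        electron_count_label=electron_count_label,
        total_energy=energy,
        charges=tuple(charges),
        energy_unit="hartree",
        method_label=method_label,
        charge_scheme_label="Hirshfeld",
    )


# ---------------------------------------------------------------------------
# Canonical JSON species document
# ---------------------------------------------------------------------------


def _state_to_json(state: ElectronicState) -> dict:
    return {
        "energy": state.total_energy,
        "energy_unit": state.energy_unit,
        "charges": list(state.charges),
        "method_label": state.method_label,
        "charge_scheme_label": state.charge_scheme_label,
    }


def _state_from_json(label: str, obj: dict) -> ElectronicState:
    return ElectronicState(
        electron_count_label=label,
        total_energy=float(obj["energy"]),
        charges=tuple(float(q) for q in obj["charges"]),
        energy_unit=obj.get("energy_unit", "hartree"),
        method_label=obj.get("method_label", ""),
        charge_scheme_label=obj.get("charge_scheme_label", "Hirshfeld"),
    )


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Write records to the canonical JSON document.

    Energies and charges are serialised with ``repr`` precision, so
    ``read_species_table(write_species_table(X)) == X`` bit-for-bit.
    """
    records = list(records)
    doc = {
        "format_version": FORMAT_VERSION,
        "index_base": 0,
        "species": [
            {
                "species_id": r.species_id,
                "alpha_atom_indices": list(r.alpha_atom_indices),
                **(
                    {"gibbs_activation_kJmol": r.gibbs_activation}
                    if r.gibbs_activation is not None
                    else {}
                ),
                "at_n_geometry": r.at_n_geometry,
                "notes": r.notes,
                "states": {
                    label: _state_to_json(r.state(label)) for label in STATE_LABELS
                },
            }
            for r in records
        ],
    }
    path = Path(path)
    try:
        with path.open("w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    except OSError as exc:
        raise ValidationError(f"cannot write species table to {path}: {exc}") from exc


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a canonical JSON species document; validate every record."""
    path = Path(path)
    try:
        with path.open() as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise ValidationError(f"cannot read species table from {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON: {exc}") from exc

    if doc.get("index_base", 0) != 0:
        raise ValidationError(f"{path}: only 0-based atom indices are supported")

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for entry in doc.get("species", []):
        sid = entry["species_id"]
        if sid in seen:
            raise ValidationError(f"{path}: duplicate species_id {sid!r}")
        seen.add(sid)
        states_obj = entry.get("states", {})
        for label in STATE_LABELS:
            if label not in states_obj:
                raise ValidationError(
                    f"{path}: species {sid!r} is missing state {label!r}"
                )
        states = tuple(
            _state_from_json(label, states_obj[label]) for label in STATE_LABELS
        )
        records.append(
            SpeciesRecord(
                species_id=sid,
                states=states,  # type: ignore[arg-type]
                alpha_atom_indices=tuple(entry["alpha_atom_indices"]),
                gibbs_activation=entry.get("gibbs_activation_kJmol"),
                notes=entry.get("notes", ""),
                at_n_geometry=entry.get("at_n_geometry", True),
            )
        )
    return records


def write_species_csv(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Tabular export: one row per species with the quantities the
    reactivity pipeline consumes (energies in hartree, charges in e)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "species_id",
                "E_N",
                "E_Nm1",
                "E_Np1",
                "q2_N",
                "q5_N",
                "q2_Np1",
                "q5_Np1",
            ]
        )
        for r in records:
            n = r.state("N")
            nm1 = r.state("N-1")
            np1 = r.state("N+1")
            for s in (n, nm1, np1):
                if s.energy_unit != "hartree":
                    raise ValidationError(
                        f"species {r.species_id!r}: CSV export requires hartree "
                        f"energies, got {s.energy_unit!r}"
                    )
            i2, i5 = r.alpha_atom_indices
            writer.writerow(
                [
                    r.species_id,
                    repr(n.total_energy),
                    repr(nm1.total_energy),
                    repr(np1.total_energy),
                    repr(n.charges[i2]),
                    repr(n.charges[i5]),
                    repr(np1.charges[i2]),
                    repr(np1.charges[i5]),
                ]
            )
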