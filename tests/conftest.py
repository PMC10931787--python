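import pytest

from thioreact.qc_state_io import ElectronicState, SpeciesRecord
from thioreact.synthetic_fixtures import FixtureSpec, generate_species


def make_record(
    species_id="sp",
    e_n=-100.0,
    e_nm1=-95.0,
    e_np1=-101.0,
    q_n=(0.10, -0.05, -0.05),
    q_nm1=(0.50, 0.30, 0.20),
    q_np1=(-0.30, -0.40, -0.30),
    unit="eV",
    alpha=(0, 1),
):
    """Hand-built species record; defaults give VIP=5, VEA=1 (eV)."""

    def state(label, energy, charges):
        return ElectronicState(
            electron_count_label=label,
            total_energy=energy,
            charges=charges,
            energy_unit=unit,
            method_label="test",
        )

    return SpeciesRecord(
        species_id=species_id,
        states=(
            state("N", e_n, q_n),
            state("N-1", e_nm1, q_nm1),
            state("N+1", e_np1, q_np1),
        ),
        alpha_atom_indices=alpha,
    )


@pytest.fixture
def hand_record():
    return make_record()


@pytest.fixture(scope="session")
def species_records():
    """A small deterministic batch of synthetic species."""
    return generate_species(FixtureSpec(seed=42, n_species=20))
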