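import numpy as np
import pytest

from barcodegap import (
    BarcodeRecord,
    SimulationConfig,
    align_by_frame,
    pairwise_matrix,
    qc_filter,
    simulate_dataset,
)

#: short stop-free COI-like fragment (frame 0, vertebrate mito code)
CLEAN_CODONS = "ATGGCACTT"


def make_record(record_id: str, sequence: str, species: str = "Genus sp1",
                genus: str | None = None, family: str = "FamilyA",
                order: str = "OrderA", class_name: str = "ClassA") -> BarcodeRecord:
    return BarcodeRecord(
        record_id=record_id,
        sequence=sequence,
        species=species,
        genus=genus or species.split()[0],
        family=family,
        order=order,
        class_name=class_name,
    )


def clean_orf(length: int, seed: int = 0) -> str:
    """Random frame-0 stop-free sequence under the vertebrate mito code."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "AGA", "AGG"}
    bases = "ACGT"
    codons = []
    while 3 * len(codons) < length:
        codon = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)[:length]


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_families=3, genera_per_family=2, species_per_genus=2,
        individuals_per_species=3, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """36 simulated records, their alignment and K2P matrix."""
    records, truth = simulate_dataset(small_config)
    passing, _ = qc_filter(records)
    aligned = align_by_frame(passing)
    matrix = pairwise_matrix(aligned)
    return passing, aligned, matrix, truth
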