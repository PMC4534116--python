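from __future__ import annotations

import numpy as np
import pytest

from s3deconv.io_formats import AlignmentObservation
from s3deconv.simulate import SimulationConfig, end_to_end_fixture


SMALL_CONFIG = SimulationConfig(
    genome_length_bp=30_000,
    n_genes=30,
    n_reads=1_500,
    divergence=0.10,
    error_rate=0.005,
    seed=11,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete small simulated experiment on disk (genomes, reads,
    truth, alignments) shared across the suite."""
    out = tmp_path_factory.mktemp("fixture")
    manifest = end_to_end_fixture(SMALL_CONFIG, out)
    return out, manifest


def obs(
    read_id: str,
    genome_id: str,
    state: tuple[bool, int] | None,
    start: int = 0,
) -> AlignmentObservation:
    """Shorthand observation builder: state None = unaligned, else
    (unique, mismatches)."""
    if state is None:
        return AlignmentObservation.unaligned(read_id, genome_id)
    unique, mismatches = state
    return AlignmentObservation(
        read_id=read_id,
        genome_id=genome_id,
        aligned=True,
        unique=unique,
        mismatches=mismatches,
        chrom="chr1",
        start=start,
        end=start + 50,
        strand="+",
    )


def random_observation_tables(n_reads: int, seed: int, genomes=("human", "mouse")):
    """Random per-genome observation tables covering all alignment states."""
    rng = np.random.default_rng(seed)
    tables = {g: [] for g in genomes}
    for i in range(n_reads):
        read_id = f"r{i:07d}"
        for g in genomes:
            roll = rng.random()
            if roll < 0.15:
                continue  # absent from this genome's file
            if roll < 0.25:
                tables[g].append(obs(read_id, g, None))
            else:
                unique = rng.random() < 0.85
                m = int(rng.integers(0, 5))
                tables[g].append(obs(read_id, g, (unique, m)))
    return tables
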