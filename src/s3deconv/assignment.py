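"""The S3 core: classify each read by species from per-genome alignments.

A read sequenced from a mixed two-species sample is aligned independently
to both reference genomes.  Species assignment then uses two signals:

* uniqueness within a genome (a multimapper can never be assigned), and
* the difference in mismatch counts between the genomes, which rescues
  reads that align to both genomes but clearly better to one.

The decision thresholds are ``Mu`` (max mismatches for a read seen in
only one genome), ``Ms`` (max mismatches in the winning genome for a read
seen in both) and ``D`` (minimum mismatch-count advantage required for a
rescue).  The defaults Mu=1, Ms=1, D=2 are the settings that balance
sensitivity against specificity for human/mouse separation.  Three-genome
mode requires the winner to beat every other aligned genome by >= D.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import AlignmentObservation

#: Label for reads that align acceptably to more than one species (or only
#: non-uniquely) and are therefore discarded.
AMBIGUOUS = "ambiguous"
#: Label for reads lost to quality (no alignment, or too many mismatches)
#: rather than to a species conflict.
UNASSIGNED = "unassigned"


class Reason(str, Enum):
    """Why a read received its label."""

    UNIQUE_ONLY = "unique_only"
    RESCUED_BY_DIFFERENCE = "rescued_by_difference"
    SHARED_TIE = "shared_tie"
    NOT_UNIQUE = "not_unique"
    TOO_MANY_MISMATCHES = "too_many_mismatches"
    UNALIGNED = "unaligned"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class AssignmentParams:
    """Thresholds of the mismatch-difference filter.

    Attributes map onto the pipeline flags -Mu, -Ms and -D.  ``strict``
    disables the mismatch-difference rescue entirely, so any read aligned
    in more than one genome is ambiguous.
    """

    max_mismatch_unique: int = 1  # -Mu
    max_mismatch_shared: int = 1  # -Ms
    min_mismatch_difference: int = 2  # -D
    strict: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatch_unique < 0 or self.max_mismatch_shared < 0:
            raise ConfigurationError("mismatch maxima must be >= 0")
        if self.min_mismatch_difference < 1:
            raise ConfigurationError("mismatch difference D must be >= 1")


@dataclass(frozen=True)
class ReadAssignment:
    """The verdict for one read: a genome id, 'ambiguous' or 'unassigned'."""

    read_id: str
    label: str
    reason: Reason


def classify_read(
    obs_by_genome: Mapping[str, AlignmentObservation],
    params: AssignmentParams = AssignmentParams(),
) -> ReadAssignment:
    """Apply the species-assignment decision procedure to one read.

    The procedure, for observations across >= 2 genomes:

    1. aligned nowhere -> unassigned(unaligned);
    2. aligned in exactly one genome: assign it (unique_only) if the
       alignment is unique with <= Mu mismatches; a multimapper is
       ambiguous(not_unique); too many mismatches -> unassigned;
    3. aligned in several genomes: the genome with strictly fewest
       mismatches wins only if it beats every other aligned genome by
       >= D, its alignment is unique and has <= Ms mismatches
       (rescued_by_difference); any tie, non-unique winner or rescue
       failure is ambiguous.  Non-unique alignments in losing genomes
       still count as cross-species evidence.
    """
    if len(obs_by_genome) < 2:
        raise ConfigurationError(
            "species assignment needs observations from at least two genomes"
        )
    read_id = next(iter(obs_by_genome.values())).read_id
    aligned = {g: o for g, o in obs_by_genome.items() if o.aligned}

    if not aligned:
        return ReadAssignment(read_id, UNASSIGNED, Reason.UNALIGNED)

    if len(aligned) == 1:
        genome, obs = next(iter(aligned.items()))
        if not obs.unique:
            return ReadAssignment(read_id, AMBIGUOUS, Reason.NOT_UNIQUE)
        if obs.mismatches <= params.max_mismatch_unique:
            return ReadAssignment(read_id, genome, Reason.UNIQUE_ONLY)
        return ReadAssignment(read_id, UNASSIGNED, Reason.TOO_MANY_MISMATCHES)

    if params.strict:
        return ReadAssignment(read_id, AMBIGUOUS, Reason.SHARED_TIE)

    best = min(o.mismatches for o in aligned.values())
    winners = [g for g, o in aligned.items() if o.mismatches == best]
    if len(winners) > 1:
        return ReadAssignment(read_id, AMBIGUOUS, Reason.SHARED_TIE)
    winner = winners[0]
    decisive = all(
        obs.mismatches - best >= params.min_mismatch_difference
        for g, obs in aligned.items()
        if g != winner
    )
    if decisive:
        if not aligned[winner].unique:
            return ReadAssignment(read_id, AMBIGUOUS, Reason.NOT_UNIQUE)
        if best <= params.max_mismatch_shared:
            return ReadAssignment(read_id, winner, Reason.RESCUED_BY_DIFFERENCE)
    return ReadAssignment(read_id, AMBIGUOUS, Reason.SHARED_TIE)


def assign_all(
    observations: Mapping[str, Iterable[AlignmentObservation]],
    params: AssignmentParams = AssignmentParams(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every read present in any genome's observation stream.

    Reads absent from a genome's stream are treated as unaligned there.
    Returns the assignment table (one row per read, sorted by read id)
    and per-label counts that sum to the number of distinct reads.

    The table columns are: read_id, label, reason, n_genomes_aligned and
    aligned_in (comma-joined sorted genome ids the read aligned to).
    """
    genome_ids = list(observations)
    if len(genome_ids) < 2:
        raise ConfigurationError("assignment needs at least two genomes")

    per_genome: dict[str, dict[str, AlignmentObservation]] = {}
    for genome_id, stream in observations.items():
        table: dict[str, AlignmentObservation] = {}
        for obs in stream:
            if obs.genome_id != genome_id:
                raise ConfigurationError(
                    f"observation for read {obs.read_id!r} carries genome "
                    f"{obs.genome_id!r} but was supplied under {genome_id!r}"
                )
            if obs.read_id in table:
                raise ConfigurationError(
                    f"duplicate read id {obs.read_id!r} in genome {genome_id!r}"
                )
            table[obs.read_id] = obs
        per_genome[genome_id] = table

    all_reads = sorted(set().union(*(t.keys() for t in per_genome.values())))
    counts: dict[str, int] = {g: 0 for g in genome_ids}
    counts[AMBIGUOUS] = 0
    counts[UNASSIGNED] = 0

    rows = []
    for read_id in all_reads:
        obs_by_genome = {
            g: per_genome[g].get(read_id)
            or AlignmentObservation.unaligned(read_id, g)
            for g in genome_ids
        }
        verdict = classify_read(obs_by_genome, params)
        aligned_in = sorted(g for g, o in obs_by_genome.items() if o.aligned)
        counts[verdict.label] += 1
        rows.append(
            (
                read_id,
                verdict.label,
                verdict.reason.value,
                len(aligned_in),
                ",".join(aligned_in),
            )
        )

    frame = pd.DataFrame(
        rows,
        columns=["read_id", "label", "reason", "n_genomes_aligned", "aligned_in"],
    )
    return frame, counts
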