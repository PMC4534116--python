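"""Synthetic two- or three-species RNA-seq with per-read ground truth.

Builds a pair of diverged toy genomes with orthologous gene models
(identical coordinates, sequences separated by i.i.d. substitutions at a
chosen per-bp rate), draws expression-weighted error-bearing reads from
the transcripts, and aligns them with an exhaustive substitution-only
scanner, so that the whole separation pipeline can run — and be scored
against truth — without any external data.

The default divergence of 0.10 substitutions per bp emulates the
exonic sequence divergence between human and mouse, the species pair the
separation method targets; the default error rate of 0.005 per bp is at
the upper end of Illumina substitution-error rates, and reads are 50 bp
single-end.  Reads are drawn from exon-interior positions only: the
oracle aligner is ungapped and unspliced, so junction-spanning reads
would be unalignable by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import (
    GeneModel,
    file_sha256,
    write_fasta,
    write_fastq,
    write_json,
    write_refflat,
    write_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

CHROM = "chr1"

#: Default maximum substitutions the oracle aligner reports, mirroring a
#: spliced aligner's default mismatch ceiling for short reads.
DEFAULT_MAX_MISMATCH = 10


def encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated mixed-species experiment.

    ``n_reads`` is per species; ``divergence`` is the per-bp substitution
    rate between orthologous genomes; ``mix_proportion`` is the fraction
    of the first species when a single mixed sample is generated directly
    (the standard fixture instead concatenates the two pure samples).
    """

    genome_length_bp: int = 80_000
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (1, 3)
    divergence: float = 0.10
    error_rate: float = 0.005
    read_length: int = 50
    n_reads: int = 20_000
    mix_proportion: float = 0.5
    seed: int = 0
    genome_ids: tuple[str, ...] = ("human", "mouse")

    def __post_init__(self) -> None:
        for name in ("divergence", "error_rate", "mix_proportion"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if len(self.genome_ids) < 2:
            raise ValueError("need at least two genome ids")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("invalid exons_per_gene range")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")


@dataclass
class SimulatedExperiment:
    """Genomes, annotations and divergence bookkeeping for one simulation."""

    config: SimulationConfig
    sequences: dict[str, np.ndarray]
    gene_models: dict[str, list[GeneModel]]
    substituted_positions: dict[str, np.ndarray]

    def sequence_strings(self) -> dict[str, str]:
        return {g: decode(seq) for g, seq in self.sequences.items()}


def _gene_layout(config: SimulationConfig, rng: np.random.Generator):
    """Place non-overlapping genes with exon/intron structure along chr1."""
    min_exon = config.read_length + 20
    genes = []
    cursor = int(rng.integers(60, 200))
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for j in range(n_exons):
            length = int(rng.integers(max(min_exon, 120), 301))
            exons.append((cursor, cursor + length))
            cursor += length
            if j < n_exons - 1:
                cursor += int(rng.integers(30, 151))
        cursor += int(rng.integers(60, 201))
        if cursor >= config.genome_length_bp:
            raise ValueError(
                f"genome_length_bp={config.genome_length_bp} too short for "
                f"{config.n_genes} genes (ran out at gene {i + 1})"
            )
        genes.append((f"GENE{i + 1:04d}", strand, exons))
    return genes


def simulate_genomes(config: SimulationConfig) -> SimulatedExperiment:
    """Build diverged toy genomes with orthologous annotation.

    The first genome is i.i.d. random sequence; every further genome is
    derived from it by substitutions at rate ``divergence`` drawn
    independently per genome (substituted positions are recorded).  Gene
    coordinates are identical across genomes (perfect orthologs).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 101])
    base = rng.integers(0, 4, config.genome_length_bp, dtype=np.uint8)
    layout = _gene_layout(config, rng)

    sequences: dict[str, np.ndarray] = {config.genome_ids[0]: base}
    substituted: dict[str, np.ndarray] = {
        config.genome_ids[0]: np.empty(0, dtype=np.int64)
    }
    for genome_id in config.genome_ids[1:]:
        mask = rng.random(config.genome_length_bp) < config.divergence
        seq = base.copy()
        shifts = rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)
        seq[mask] = (seq[mask] + shifts) % 4
        sequences[genome_id] = seq
        substituted[genome_id] = np.flatnonzero(mask)

    gene_models = {
        genome_id: [
            GeneModel(
                gene_id=name,
                genome_id=genome_id,
                exon_union=tuple((CHROM, s, e, strand) for s, e in exons),
                biotype_hint="protein_coding",
            )
            for name, strand, exons in layout
        ]
        for genome_id in config.genome_ids
    }
    return SimulatedExperiment(
        config=config,
        sequences=sequences,
        gene_models=gene_models,
        substituted_positions=substituted,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def expression_weights(config: SimulationConfig, genome_id: str) -> np.ndarray:
    """Per-gene lognormal(0, 1) expression weights, fixed per species.

    The weights depend only on the config seed and the species, so every
    sample drawn from the same simulated species shares one expression
    profile (as pure and mixed aliquots of one RNA pool would).
    """
    gidx = list(config.genome_ids).index(genome_id)
    rng = np.random.default_rng([config.seed, 202, gidx])
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    return weights / weights.sum()


def simulate_reads(
    experiment: SimulatedExperiment,
    sample_id: str,
    genome_id: str | None = None,
    n_reads: int | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw error-bearing reads with truth records.

    ``genome_id=None`` generates a mixed sample: each read's species is
    the first genome with probability ``mix_proportion``, else the
    second.  Reads are uniform over exon-interior start positions of a
    gene chosen by its expression weight; substitution errors occur at
    ``error_rate`` per bp.  Returns ([(read_id, sequence)], truth table
    with read_id, genome_id, gene_id, chrom, position, strand, n_errors).
    """
    config = experiment.config
    k = config.read_length
    rng = np.random.default_rng([config.seed, 303, seed])
    n = config.n_reads if n_reads is None else n_reads

    if genome_id is None:
        species_pool = list(config.genome_ids[:2])
        choice = rng.random(n) < config.mix_proportion
        species_per_read = [species_pool[0] if c else species_pool[1] for c in choice]
    else:
        if genome_id not in config.genome_ids:
            raise ValueError(f"unknown genome {genome_id!r}")
        species_per_read = [genome_id] * n

    # Per species: gene sampling weights and exon-interior start tables.
    per_species: dict[str, tuple] = {}
    for gid in set(species_per_read):
        models = experiment.gene_models[gid]
        weights = expression_weights(config, gid)
        starts_per_gene = []
        for model in models:
            starts = []
            for _, s, e, _ in model.exon_union:
                if e - s >= k:
                    starts.append((s, e - k + 1))  # valid start range
            starts_per_gene.append(starts)
        n_starts = np.array(
            [sum(hi - lo for lo, hi in sp) for sp in starts_per_gene], dtype=float
        )
        usable = n_starts > 0
        w = weights * usable
        if w.sum() == 0:
            raise ValueError(f"no gene of {gid} can host a {k} bp read")
        per_species[gid] = (models, w / w.sum(), starts_per_gene)

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i, gid in enumerate(species_per_read):
        models, gene_p, starts_per_gene = per_species[gid]
        g = int(rng.choice(len(models), p=gene_p))
        ranges = starts_per_gene[g]
        sizes = np.array([hi - lo for lo, hi in ranges])
        offset = int(rng.integers(0, sizes.sum()))
        for (lo, hi), size in zip(ranges, sizes):
            if offset < size:
                pos = lo + offset
                break
            offset -= size
        codes = experiment.sequences[gid][pos : pos + k].copy()
        strand = models[g].exon_union[0][3]
        if strand == "-":
            codes = revcomp(codes)
        err_mask = rng.random(k) < config.error_rate
        n_err = int(err_mask.sum())
        if n_err:
            codes[err_mask] = (
                codes[err_mask] + rng.integers(1, 4, n_err, dtype=np.uint8)
            ) % 4
        read_id = f"{sample_id}:{i:07d}"
        reads.append((read_id, decode(codes)))
        truth_rows.append(
            (read_id, gid, models[g].gene_id, CHROM, pos, strand, n_err)
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "genome_id", "gene_id", "chrom", "position", "strand", "n_errors"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Exhaustive substitution-only aligner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    pos: int
    strand: str
    mismatches: int


class _SeedIndex:
    """Sorted k-mer index over one genome for pigeonhole candidate lookup."""

    def __init__(self, genome: np.ndarray, seed_len: int):
        self.seed_len = seed_len
        windows = sliding_window_view(genome, seed_len).astype(np.int64)
        powers = 4 ** np.arange(seed_len, dtype=np.int64)
        ids = windows @ powers
        self.order = np.argsort(ids, kind="stable").astype(np.int64)
        self.sorted_ids = ids[self.order]


def _segment_ranges(lengths: np.ndarray) -> np.ndarray:
    """[0..l0), [0..l1), ... concatenated, for variable-length gathers."""
    total = int(lengths.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.cumsum(lengths) - lengths
    return np.arange(total, dtype=np.int64) - np.repeat(starts, lengths)


def _candidate_positions(
    index: _SeedIndex,
    read_codes: np.ndarray,
    genome_len: int,
    max_mismatch: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate (read_idx, genome_pos) pairs by the pigeonhole principle.

    Each read is cut into ``max_mismatch + 1`` disjoint seeds; any
    placement within the mismatch budget must match at least one seed
    exactly, so looking every seed up in the genome index is exhaustive.
    """
    n_reads, k = read_codes.shape
    s = index.seed_len
    n_seeds = max_mismatch + 1
    offsets = (np.arange(n_seeds) * s).astype(np.int64)
    powers = 4 ** np.arange(s, dtype=np.int64)
    seed_ids = np.empty((n_reads, n_seeds), dtype=np.int64)
    for j, off in enumerate(offsets):
        seed_ids[:, j] = read_codes[:, off : off + s].astype(np.int64) @ powers

    lo = np.searchsorted(index.sorted_ids, seed_ids)
    hi = np.searchsorted(index.sorted_ids, seed_ids, side="right")
    lengths = (hi - lo).ravel()
    idx_into_order = np.repeat(lo.ravel(), lengths) + _segment_ranges(lengths)
    positions = index.order[idx_into_order]
    positions = positions - np.repeat(np.tile(offsets, n_reads), lengths)
    read_idx = np.repeat(
        np.repeat(np.arange(n_reads, dtype=np.int64), n_seeds), lengths
    )
    valid = (positions >= 0) & (positions <= genome_len - k)
    return read_idx[valid], positions[valid]


def _verify_candidates(
    genome_windows: np.ndarray,
    read_codes: np.ndarray,
    read_idx: np.ndarray,
    positions: np.ndarray,
    max_mismatch: int,
    chunk: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hamming-verify candidates; keep those within the mismatch budget.

    ``genome_windows`` is a zero-copy sliding-window view of the genome
    with one row per placement start, so a candidate is verified by one
    row gather plus a vectorized compare.
    """
    kept_r, kept_p, kept_m = [], [], []
    for start in range(0, len(positions), chunk):
        pos_c = positions[start : start + chunk]
        ridx_c = read_idx[start : start + chunk]
        windows = genome_windows[pos_c]
        mm = (windows != read_codes[ridx_c]).sum(axis=1)
        ok = mm <= max_mismatch
        kept_r.append(ridx_c[ok])
        kept_p.append(pos_c[ok])
        kept_m.append(mm[ok].astype(np.int64))
    if not kept_r:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    return np.concatenate(kept_r), np.concatenate(kept_p), np.concatenate(kept_m)


def _best_placements_batch(
    fwd: np.ndarray,
    rev: np.ndarray,
    index: _SeedIndex,
    genome_windows: np.ndarray,
    genome_len: int,
    budget: int,
    max_mismatch: int,
) -> list[list[Placement] | None]:
    """Best placements per read from one pigeonhole pass at ``budget``.

    The pass is exhaustive for placements with <= ``budget`` mismatches;
    a read whose best discovered hit exceeds the budget (or that has no
    hit at all while budget < max_mismatch) is returned as None, meaning
    "unresolved: escalate to a finer pass".
    """
    n_reads = fwd.shape[0]
    hits: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]] = []
    for codes, strand_code in ((fwd, 0), (rev, 1)):
        ridx, pos = _candidate_positions(index, codes, genome_len, budget)
        ridx, pos, mm = _verify_candidates(genome_windows, codes, ridx, pos, max_mismatch)
        if len(ridx):
            # dedupe (read, pos) pairs discovered via several seeds
            key = ridx * (genome_len + 1) + pos
            _, first = np.unique(key, return_index=True)
            hits.append((ridx[first], pos[first], mm[first], strand_code))

    final = budget >= max_mismatch
    results: list[list[Placement] | None] = [([] if final else None)] * n_reads
    if not hits:
        return results
    all_r = np.concatenate([h[0] for h in hits])
    all_p = np.concatenate([h[1] for h in hits])
    all_m = np.concatenate([h[2] for h in hits])
    all_s = np.concatenate([np.full(len(h[0]), h[3]) for h in hits])
    order = np.lexsort((all_p, all_s, all_m, all_r))
    all_r, all_p, all_m, all_s = all_r[order], all_p[order], all_m[order], all_s[order]
    boundaries = np.flatnonzero(np.diff(all_r)) + 1
    group_starts = np.concatenate(([0], boundaries))
    group_ends = np.concatenate((boundaries, [len(all_r)]))
    for gs, ge in zip(group_starts, group_ends):
        best = all_m[gs]
        if best > budget and not final:
            continue  # a better placement may exist beyond this pass's reach
        placements = []
        for i in range(gs, ge):
            if all_m[i] != best:
                break
            placements.append(
                Placement(
                    pos=int(all_p[i]),
                    strand="+" if all_s[i] == 0 else "-",
                    mismatches=int(all_m[i]),
                )
            )
        results[all_r[gs]] = placements
    return results


def align_reads(
    read_seqs: Sequence[str],
    genome: np.ndarray | str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    batch_size: int = 4000,
) -> list[list[Placement]]:
    """Exhaustively align reads against both strands of a genome.

    For every read, finds ALL placements with <= ``max_mismatch``
    substitutions (no gaps) and returns the co-optimal best placements
    (minimum mismatch count; ties on mismatches are all reported,
    ordered by strand then position).  An empty list means unaligned.

    The search runs coarse-to-fine pigeonhole passes (mismatch budgets
    4, 7, then ``max_mismatch``): a pass with budget m splits each read
    into m+1 disjoint seeds, so any placement within m mismatches must
    contain an exact seed and the pass is provably exhaustive up to m.
    Reads whose best hit fits the budget are done; the rest escalate to
    the next pass with shorter seeds (more candidates).  Most reads
    resolve in the cheap first pass; results are identical to a full
    scan.
    """
    if isinstance(genome, str):
        genome = encode(genome)
    if not len(read_seqs):
        return []
    k = len(read_seqs[0])
    if any(len(s) != k for s in read_seqs):
        raise ValueError("all reads must have equal length")
    if k > len(genome):
        raise ValueError("read longer than genome")
    if k // (max_mismatch + 1) < 1:
        raise ValueError(f"max_mismatch={max_mismatch} too large for read length {k}")
    L = len(genome)
    genome_windows = sliding_window_view(genome, k)
    budgets = sorted({min(b, max_mismatch) for b in (4, 7, max_mismatch)})
    indices = {b: _SeedIndex(genome, k // (b + 1)) for b in budgets}

    fwd = np.stack([encode(s) for s in read_seqs])
    rev = np.stack([revcomp(r) for r in fwd])

    results: list[list[Placement]] = [[] for _ in read_seqs]
    unresolved = np.arange(len(read_seqs))
    for budget in budgets:
        if len(unresolved) == 0:
            break
        still: list[int] = []
        for start in range(0, len(unresolved), batch_size):
            subset = unresolved[start : start + batch_size]
            batch = _best_placements_batch(
                fwd[subset],
                rev[subset],
                indices[budget],
                genome_windows,
                L,
                budget,
                max_mismatch,
            )
            for read_i, placements in zip(subset, batch):
                if placements is None:
                    still.append(read_i)
                else:
                    results[read_i] = placements
        unresolved = np.array(still, dtype=int)
    return results


def align_observations(
    reads: Sequence[tuple[str, str]],
    genome: np.ndarray,
    genome_id: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list:
    """Align reads in memory and collapse to one observation per read.

    Equivalent to ``oracle_align`` followed by ``read_alignments`` but
    without the SAM round trip; the primary placement (first co-optimal
    hit) provides the location, and uniqueness means a single co-optimal
    placement.
    """
    from .io_formats import AlignmentObservation

    placements = align_reads([seq for _, seq in reads], genome, max_mismatch)
    out = []
    for (read_id, seq), hits in zip(reads, placements):
        if not hits:
            out.append(AlignmentObservation.unaligned(read_id, genome_id))
            continue
        top = hits[0]
        out.append(
            AlignmentObservation(
                read_id=read_id,
                genome_id=genome_id,
                aligned=True,
                unique=len(hits) == 1,
                mismatches=top.mismatches,
                chrom=CHROM,
                start=top.pos,
                end=top.pos + len(seq),
                strand=top.strand,
            )
        )
    return out


def write_sam(
    reads: Sequence[tuple[str, str]],
    placements: Sequence[list[Placement]],
    genome_length: int,
    path: str | Path,
) -> None:
    """Write best placements as SAM with NM/NH tags and the MAPQ-255
    unique-alignment convention (multimappers get MAPQ 3)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": CHROM, "LN": int(genome_length)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for (read_id, seq), hits in zip(reads, placements):
            if not hits:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read_id
                rec.flag = 4
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(rec)
                continue
            nh = len(hits)
            for rank, hit in enumerate(hits):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read_id
                rec.flag = (16 if hit.strand == "-" else 0) | (256 if rank else 0)
                rec.reference_id = 0
                rec.reference_start = hit.pos
                rec.mapping_quality = 255 if nh == 1 else 3
                rec.cigarstring = f"{len(seq)}M"
                stored = seq if hit.strand == "+" else decode(revcomp(encode(seq)))
                rec.query_sequence = stored
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                rec.set_tag("NM", hit.mismatches)
                rec.set_tag("NH", nh)
                out.write(rec)


def oracle_align(
    reads_fastq: str | Path,
    genome_fasta: str | Path,
    out_sam: str | Path,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> None:
    """File-level wrapper: FASTQ + FASTA in, SAM with best placements out."""
    from .io_formats import read_fasta, read_fastq

    reads = read_fastq(reads_fastq)
    genome_by_name = read_fasta(genome_fasta)
    if len(genome_by_name) != 1:
        raise ValueError("oracle aligner expects a single-sequence genome FASTA")
    genome = encode(next(iter(genome_by_name.values())))
    placements = align_reads([seq for _, seq in reads], genome, max_mismatch)
    write_sam(reads, placements, len(genome), out_sam)


# ---------------------------------------------------------------------------
# One-call fixture
# ---------------------------------------------------------------------------

def end_to_end_fixture(
    config: SimulationConfig,
    out_dir: str | Path,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    include_pure: bool = True,
) -> dict:
    """Produce every file the separation pipeline consumes, plus truth.

    Writes per-genome FASTA and refFlat, one pure FASTQ per species
    (``n_reads`` reads each) with truth tables, the mixed sample as the
    concatenation of the pure samples (mirroring in-silico mixing of two
    sequenced samples), and SAM alignments of every sample against every
    genome.  A manifest JSON records the config and per-file SHA-256
    hashes; re-running with the same config reproduces identical hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    experiment = simulate_genomes(config)
    files: dict[str, str] = {}

    for gid, seq in experiment.sequences.items():
        fasta = out / f"{gid}.fa"
        write_fasta({CHROM: decode(seq)}, fasta)
        files[fasta.name] = file_sha256(fasta)
        refflat = out / f"{gid}.refflat"
        write_refflat(experiment.gene_models[gid], refflat)
        files[refflat.name] = file_sha256(refflat)

    two_species = list(config.genome_ids[:2])
    samples: dict[str, tuple[list[tuple[str, str]], pd.DataFrame]] = {}
    for i, gid in enumerate(two_species):
        reads, truth = simulate_reads(
            experiment, sample_id=f"pure_{gid}", genome_id=gid, seed=11 + i
        )
        samples[f"pure_{gid}"] = (reads, truth)

    mix_reads = [r for gid in two_species for r in samples[f"pure_{gid}"][0]]
    mix_truth = pd.concat(
        [samples[f"pure_{gid}"][1] for gid in two_species], ignore_index=True
    )
    samples["mix"] = (mix_reads, mix_truth)

    sample_names = ["mix"] + (
        [f"pure_{gid}" for gid in two_species] if include_pure else []
    )

    # Align each pure sample once per genome; the mix reuses those hits.
    placements_cache: dict[tuple[str, str], list[list[Placement]]] = {}
    for gid in config.genome_ids:
        genome = experiment.sequences[gid]
        for pure in (f"pure_{g}" for g in two_species):
            reads, _ = samples[pure]
            placements_cache[(pure, gid)] = align_reads(
                [seq for _, seq in reads], genome, max_mismatch
            )
        placements_cache[("mix", gid)] = [
            hit
            for pure in (f"pure_{g}" for g in two_species)
            for hit in placements_cache[(pure, gid)]
        ]

    for name in sample_names:
        reads, truth = samples[name]
        fastq = out / f"{name}.fastq"
        write_fastq(reads, fastq)
        files[fastq.name] = file_sha256(fastq)
        truth_path = out / f"{name}.truth.tsv"
        write_table(truth, truth_path)
        files[truth_path.name] = file_sha256(truth_path)
        for gid in config.genome_ids:
            sam = out / f"{name}.{gid}.sam"
            write_sam(
                reads,
                placements_cache[(name, gid)],
                config.genome_length_bp,
                sam,
            )
            files[sam.name] = file_sha256(sam)

    manifest = {
        "config": {
            **{
                key: (list(value) if isinstance(value, tuple) else value)
                for key, value in asdict(config).items()
            }
        },
        "max_mismatch": max_mismatch,
        "samples": sample_names,
        "genomes": list(config.genome_ids),
        "files": files,
    }
    write_json(manifest, out / "manifest.json")
    return manifest
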