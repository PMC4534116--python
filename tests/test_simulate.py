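"""Simulator properties: genome divergence, read truth, aligner exactness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from oracles import naive_best_placements, revcomp_str
from s3deconv.io_formats import read_alignments, read_fasta, read_fastq
from s3deconv.simulate import (
    CHROM,
    SimulationConfig,
    align_reads,
    decode,
    encode,
    end_to_end_fixture,
    expression_weights,
    oracle_align,
    revcomp,
    simulate_genomes,
    simulate_reads,
    write_sam,
)

TINY = SimulationConfig(
    genome_length_bp=15_000, n_genes=12, n_reads=800, seed=3
)


class TestGenomes:
    def test_zero_divergence_identical_sequences(self):
        cfg = SimulationConfig(
            genome_length_bp=15_000, n_genes=12, divergence=0.0, seed=3
        )
        exp = simulate_genomes(cfg)
        assert np.array_equal(exp.sequences["human"], exp.sequences["mouse"])
        assert len(exp.substituted_positions["mouse"]) == 0

    def test_substitution_count_within_four_sigma(self):
        cfg = SimulationConfig(genome_length_bp=40_000, n_genes=12, seed=4)
        exp = simulate_genomes(cfg)
        n_sub = (exp.sequences["human"] != exp.sequences["mouse"]).sum()
        expected = cfg.divergence * cfg.genome_length_bp
        sigma = np.sqrt(cfg.genome_length_bp * cfg.divergence * (1 - cfg.divergence))
        assert abs(n_sub - expected) < 4 * sigma
        assert n_sub == len(exp.substituted_positions["mouse"])

    def test_orthologous_coordinates(self):
        exp = simulate_genomes(TINY)
        assert [m.exon_union for m in exp.gene_models["human"]] == [
            m.exon_union for m in exp.gene_models["mouse"]
        ]

    def test_deterministic_under_seed(self):
        a = simulate_genomes(TINY)
        b = simulate_genomes(TINY)
        assert np.array_equal(a.sequences["mouse"], b.sequences["mouse"])

    def test_genome_too_short_for_genes(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_genomes(SimulationConfig(genome_length_bp=2_000, n_genes=50))

    def test_three_genome_mode(self):
        cfg = SimulationConfig(
            genome_length_bp=15_000,
            n_genes=12,
            seed=5,
            genome_ids=("human", "mouse", "rat"),
        )
        exp = simulate_genomes(cfg)
        assert set(exp.sequences) == {"human", "mouse", "rat"}
        assert not np.array_equal(exp.sequences["mouse"], exp.sequences["rat"])


class TestReads:
    def test_pure_sample_all_from_one_species(self):
        exp = simulate_genomes(TINY)
        _, truth = simulate_reads(exp, "s", genome_id="mouse", seed=1)
        assert (truth["genome_id"] == "mouse").all()

    def test_mix_proportion_one_means_first_species_only(self):
        cfg = SimulationConfig(
            genome_length_bp=15_000, n_genes=12, n_reads=500, mix_proportion=1.0, seed=3
        )
        exp = simulate_genomes(cfg)
        _, truth = simulate_reads(exp, "s", seed=2)
        assert (truth["genome_id"] == "human").all()

    def test_error_free_reads_are_exact_genome_substrings(self):
        cfg = SimulationConfig(
            genome_length_bp=15_000, n_genes=12, n_reads=400, error_rate=0.0, seed=3
        )
        exp = simulate_genomes(cfg)
        reads, truth = simulate_reads(exp, "s", genome_id="human", seed=3)
        genome = decode(exp.sequences["human"])
        for (read_id, seq), row in zip(reads, truth.itertuples()):
            window = genome[row.position : row.position + cfg.read_length]
            assert seq == (window if row.strand == "+" else revcomp_str(window))
        assert (truth["n_errors"] == 0).all()

    def test_per_gene_counts_match_expression_weights(self):
        cfg = SimulationConfig(
            genome_length_bp=40_000, n_genes=25, n_reads=20_000, seed=6
        )
        exp = simulate_genomes(cfg)
        _, truth = simulate_reads(exp, "s", genome_id="human", seed=4)
        weights = expression_weights(cfg, "human")
        gene_ids = [m.gene_id for m in exp.gene_models["human"]]
        observed = truth["gene_id"].value_counts().reindex(gene_ids).fillna(0)
        expected = weights / weights.sum() * len(truth)
        keep = expected > 5  # chi-square validity
        stat, p = chisquare(observed[keep], expected[keep] * observed[keep].sum()
                            / expected[keep].sum())
        assert p > 0.001


class TestAligner:
    def test_agrees_with_naive_double_implementation(self):
        rng = np.random.default_rng(11)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        genome += genome[100:170]  # a duplicated segment
        reads = []
        for _ in range(25):
            pos = int(rng.integers(0, len(genome) - 40))
            codes = encode(genome[pos : pos + 40])
            for _ in range(int(rng.integers(0, 6))):
                i = int(rng.integers(0, 40))
                codes[i] = (codes[i] + int(rng.integers(1, 4))) % 4
            if rng.random() < 0.5:
                codes = revcomp(codes)
            reads.append(decode(codes))
        for max_mm in (2, 10):
            got = align_reads(reads, genome, max_mismatch=max_mm)
            for read, hits in zip(reads, got):
                mine = sorted(
                    ((h.pos, h.strand, h.mismatches) for h in hits),
                    key=lambda h: (h[1], h[0]),
                )
                assert mine == naive_best_placements(read, genome, max_mm)

    def test_exact_unique_substring_conventions(self, tmp_path):
        rng = np.random.default_rng(12)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        reads = [("r1", genome[100:150])]
        placements = align_reads([genome[100:150]], genome)
        write_sam(reads, placements, len(genome), tmp_path / "a.sam")
        (obs,) = list(read_alignments(tmp_path / "a.sam", "g"))
        assert obs.unique and obs.mismatches == 0 and obs.start == 100

    def test_duplicated_segment_multimaps(self, tmp_path):
        rng = np.random.default_rng(13)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        genome = core + core[50:120] + core[300:]
        read = core[60:110]
        placements = align_reads([read], genome)
        assert len(placements[0]) >= 2
        write_sam([("r1", read)], placements, len(genome), tmp_path / "m.sam")
        (obs,) = list(read_alignments(tmp_path / "m.sam", "g"))
        assert obs.aligned and not obs.unique

    def test_read_longer_than_genome(self):
        with pytest.raises(ValueError, match="longer than genome"):
            align_reads(["ACGTACGT"], "ACG")

    def test_oracle_align_file_round_trip(self, fixture_dir):
        out, _ = fixture_dir
        sam = out / "recheck.sam"
        oracle_align(out / "pure_human.fastq", out / "human.fa", sam)
        reread = {o.read_id: o for o in read_alignments(sam, "human")}
        original = {
            o.read_id: o for o in read_alignments(out / "pure_human.human.sam", "human")
        }
        assert reread == original


class TestFixture:
    def test_manifest_hashes_reproducible(self, tmp_path):
        cfg = SimulationConfig(genome_length_bp=12_000, n_genes=10, n_reads=200, seed=9)
        m1 = end_to_end_fixture(cfg, tmp_path / "a")
        m2 = end_to_end_fixture(cfg, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_fixture_contents_are_consistent(self, fixture_dir):
        out, manifest = fixture_dir
        genomes = read_fasta(out / "human.fa")
        assert set(genomes) == {CHROM}
        mix = read_fastq(out / "mix.fastq")
        pure_h = read_fastq(out / "pure_human.fastq")
        pure_m = read_fastq(out / "pure_mouse.fastq")
        # the mixed sample is the concatenation of the pure samples
        assert mix == pure_h + pure_m
        assert set(manifest["files"]) >= {
            "mix.fastq", "mix.truth.tsv", "mix.human.sam", "mix.mouse.sam"
        }

    def test_ambiguity_decreases_along_divergence_ladder(self):
        """More inter-genome divergence leaves fewer reads ambiguous."""
        from s3deconv.assignment import AMBIGUOUS, AssignmentParams, assign_all
        from s3deconv.simulate import align_observations

        fractions = []
        for divergence in (0.0, 0.002, 0.01, 0.05):
            cfg = SimulationConfig(
                genome_length_bp=15_000,
                n_genes=12,
                n_reads=600,
                divergence=divergence,
                seed=21,
            )
            exp = simulate_genomes(cfg)
            reads, _ = simulate_reads(exp, "s", genome_id="human", seed=5)
            obs = {
                g: align_observations(reads, exp.sequences[g], g)
                for g in cfg.genome_ids
            }
            frame, counts = assign_all(obs, AssignmentParams())
            fractions.append(counts[AMBIGUOUS] / len(frame))
        assert fractions[0] > fractions[1] > fractions[2] > fractions[3]
        assert fractions[0] > 0.99  # identical genomes: everything ambiguous
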