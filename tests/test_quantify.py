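"""Counting, masking, RPKM and TMM normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from oracles import brute_force_counts, brute_force_tmm
from s3deconv.io_formats import GeneModel
from s3deconv.quantify import (
    count_reads,
    detected_genes,
    expression_matrix,
    filter_small_rna,
    mask_name_overlaps,
    rpkm,
    tmm_factors,
)


def model(gene_id, exons, biotype="", genome_id="human"):
    return GeneModel(
        gene_id=gene_id,
        genome_id=genome_id,
        exon_union=tuple(("chr1", s, e, "+") for s, e in exons),
        biotype_hint=biotype,
    )


class TestMasking:
    def test_shared_region_removed_from_both(self):
        models = [model("G1", [(0, 100)]), model("G2", [(50, 150)])]
        masked, dropped = mask_name_overlaps(models)
        assert dropped == []
        lengths = {m.gene_id: m.effective_length_bp for m in masked}
        assert lengths == {"G1": 50, "G2": 50}
        assert masked[0].exon_union == (("chr1", 0, 50, "+"),)
        assert masked[1].exon_union == (("chr1", 100, 150, "+"),)

    def test_disjoint_genes_unchanged(self):
        models = [model("G1", [(0, 100)]), model("G2", [(200, 300)])]
        masked, dropped = mask_name_overlaps(models)
        assert dropped == []
        assert [m.exon_union for m in masked] == [m.exon_union for m in models]

    def test_identical_duplicate_genes_both_dropped(self):
        models = [model("G1", [(0, 100)]), model("G2", [(0, 100)])]
        masked, dropped = mask_name_overlaps(models)
        assert masked == []
        assert sorted(dropped) == ["G1", "G2"]

    def test_order_independent_and_idempotent(self):
        models = [
            model("G1", [(0, 100), (150, 250)]),
            model("G2", [(80, 180)]),
            model("G3", [(400, 500)]),
        ]
        masked_fwd, _ = mask_name_overlaps(models)
        masked_rev, _ = mask_name_overlaps(models[::-1])
        assert {m.gene_id: m.exon_union for m in masked_fwd} == {
            m.gene_id: m.exon_union for m in masked_rev
        }
        again, dropped = mask_name_overlaps(masked_fwd)
        assert dropped == []
        assert [m.exon_union for m in again] == [m.exon_union for m in masked_fwd]


class TestCounting:
    def test_read_inside_single_gene(self):
        counts = count_reads(
            pd.DataFrame([("r1", "chr1", 10, 60)],
                         columns=["read_id", "chrom", "start", "end"]),
            [model("G1", [(0, 100)])],
        )
        assert counts["G1"] == 1

    def test_read_in_masked_region_counts_nowhere(self):
        models, _ = mask_name_overlaps(
            [model("G1", [(0, 100)]), model("G2", [(0, 100), (200, 300)])]
        )
        counts = count_reads(
            pd.DataFrame([("r1", "chr1", 20, 70)],
                         columns=["read_id", "chrom", "start", "end"]),
            models,
        )
        assert counts.sum() == 0

    def test_against_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(5)
        gene_exons = {}
        models = []
        cursor = 0
        for i in range(12):
            exons = []
            for _ in range(int(rng.integers(1, 3))):
                start = cursor + int(rng.integers(0, 30))
                end = start + int(rng.integers(40, 120))
                exons.append(("chr1", start, end))
                cursor = end + int(rng.integers(0, 40))
            gene_exons[f"G{i}"] = exons
            models.append(model(f"G{i}", [(s, e) for _, s, e in exons]))
        reads = []
        for j in range(400):
            start = int(rng.integers(0, cursor))
            reads.append((f"r{j}", "chr1", start, start + 50))
        frame = pd.DataFrame(reads, columns=["read_id", "chrom", "start", "end"])
        got = count_reads(frame, models)
        want = brute_force_counts(reads, gene_exons)
        assert got.to_dict() == want

    def test_no_models_is_an_error(self):
        with pytest.raises(ValueError):
            count_reads(pd.DataFrame(columns=["read_id", "chrom", "start", "end"]), [])


class TestRpkm:
    def test_unit_case(self):
        value = rpkm(
            pd.Series({"G1": 10}), pd.Series({"G1": 1000}), total_assigned_reads=1e6
        )
        assert value["G1"] == pytest.approx(10.0)

    def test_zero_counts_zero_rpkm(self):
        value = rpkm(pd.Series({"G1": 0}), pd.Series({"G1": 1000}), 1e6)
        assert value["G1"] == 0.0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [5, 20, 0]}, index=["a", "b", "c"])
        lengths = pd.Series({"a": 500, "b": 2000, "c": 800})
        base = rpkm(counts, lengths)
        doubled = rpkm(counts * 2, lengths, total_assigned_reads=counts.sum() * 2)
        pd.testing.assert_frame_equal(base, doubled)


class TestSmallRnaFilter:
    @pytest.mark.parametrize(
        "gene_id,removed",
        [
            ("MIR21", True),
            ("SNORD14", True),
            ("SNORA5A", True),
            ("MIRLET7A", True),
            ("mir142", True),
            ("MIRROR1", False),
            ("SNORKEL", False),
            ("ACTB", False),
        ],
    )
    def test_symbol_fallback_rule(self, gene_id, removed):
        kept, gone = filter_small_rna([model(gene_id, [(0, 100)])])
        assert (gene_id in gone) == removed

    def test_biotype_hint_takes_precedence(self):
        kept, gone = filter_small_rna(
            [model("WEIRDNAME", [(0, 100)], biotype="miRNA"),
             model("OTHER", [(0, 100)], biotype="snoRNA"),
             model("KEEPME", [(0, 100)], biotype="protein_coding")],
        )
        assert sorted(gone) == ["OTHER", "WEIRDNAME"]
        assert [m.gene_id for m in kept] == ["KEEPME"]


def test_detection_cutoff():
    counts = pd.Series({"a": 0, "b": 1, "c": 5})
    assert detected_genes(counts).to_dict() == {"a": False, "b": True, "c": True}
    assert detected_genes(counts, cutoff=2).to_dict() == {
        "a": False,
        "b": False,
        "c": True,
    }


class TestTmm:
    def test_identical_samples_factor_one(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(1, 1, 300)
        matrix = pd.DataFrame({"s1": col, "s2": col})
        factors = tmm_factors(matrix)
        assert factors.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_global_doubling_closed_form(self):
        """All M equal log2(2), so factors must be (1/sqrt 2, sqrt 2)."""
        rng = np.random.default_rng(1)
        col = rng.lognormal(1, 1, 300)
        matrix = pd.DataFrame({"s1": col, "s2": 2 * col})
        factors = tmm_factors(matrix)
        assert factors["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
        assert factors["s2"] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(0, 1.2, size=(400, 4))
        values[rng.random(values.shape) < 0.15] = 0.0
        values[:, 0] += 0.01  # keep the reference well-populated
        matrix = pd.DataFrame(values, columns=list("abcd"))
        got = tmm_factors(matrix, reference="a")
        raw = brute_force_tmm(values, ref=0)
        want = raw / gmean(raw)
        assert got.to_numpy() == pytest.approx(want, rel=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.lognormal(0, 1, size=(200, 3)), columns=list("xyz"))
        factors = tmm_factors(matrix)
        assert gmean(factors) == pytest.approx(1.0, rel=1e-12)

    def test_errors(self):
        one = pd.DataFrame({"s1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tmm_factors(one)
        zero = pd.DataFrame({"s1": [1.0, 2.0], "dead": [0.0, 0.0]})
        with pytest.raises(ValueError, match="dead"):
            tmm_factors(zero)


def test_expression_matrix_invariants():
    models = [model("G1", [(0, 1000)]), model("G2", [(2000, 2500)])]
    counts = {
        "s1": pd.Series({"G1": 10, "G2": 0}),
        "s2": pd.Series({"G1": 7, "G2": 3}),
    }
    expr = expression_matrix(counts, models, genome_id="human")
    assert ((expr.rpkm == 0) == (expr.counts == 0)).all().all()
    assert gmean(expr.tmm_factor) == pytest.approx(1.0)
    assert expr.total_assigned_reads.to_dict() == {"s1": 10, "s2": 10}
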