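"""Gene-level quantification of species-assigned reads.

Implements exon-union counting with name-overlap masking, RPKM, removal
of small structural RNAs (miRNA/snoRNA), the 1-read detection cutoff and
TMM (trimmed mean of M-values) normalization between samples.

Counting rule: a read is counted to a gene when its alignment interval
overlaps the gene's masked exon union by at least 1 bp (a read hanging
over either gene end still counts in full).  Base pairs claimed by the
exon unions of two or more distinct gene ids are masked out of all of
them before counting, so reads from such regions are counted to no gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import gmean, rankdata

from .io_formats import AlignmentObservation, GeneModel, merge_intervals

#: Gene symbols matching this pattern are treated as miRNA/snoRNA when the
#: annotation carries no biotype: the prefix must be followed by a digit
#: (optionally after a snoRNA class letter) or by LET, so that e.g.
#: "MIRROR"-like symbols survive.
_SMALL_RNA_SYMBOL = re.compile(r"^(MIRLET|MIR\d|SNOR[DA]?\d)", re.IGNORECASE)
_SMALL_RNA_BIOTYPES = {"mirna", "snorna"}


# ---------------------------------------------------------------------------
# Gene-model preparation
# ---------------------------------------------------------------------------

def filter_small_rna(
    gene_models: Sequence[GeneModel],
) -> tuple[list[GeneModel], list[str]]:
    """Drop microRNA and snoRNA genes before counting.

    A gene is removed when its annotation biotype says miRNA/snoRNA, or,
    as a fallback for annotations without biotypes, when its symbol has a
    MIR/MIRLET/SNOR prefix followed by a digit or LET.
    Returns (kept models, removed gene ids).
    """
    kept, removed = [], []
    for model in gene_models:
        if model.biotype_hint.lower() in _SMALL_RNA_BIOTYPES or _SMALL_RNA_SYMBOL.match(
            model.gene_id
        ):
            removed.append(model.gene_id)
        else:
            kept.append(model)
    return kept, removed


def _subtract(
    intervals: Sequence[tuple[int, int]], masked: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Difference of sorted disjoint interval lists on one chromosome."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in intervals:
        cur = s
        while j < len(masked) and masked[j][1] <= s:
            j += 1
        k = j
        while k < len(masked) and masked[k][0] < e:
            ms, me = masked[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def mask_name_overlaps(
    gene_models: Sequence[GeneModel],
) -> tuple[list[GeneModel], list[str]]:
    """Remove every bp claimed by >= 2 distinct gene ids from all of them.

    Genes left with zero exonic length (e.g. exact duplicates) are dropped
    from quantification and reported in the second return value.  The
    operation is order-independent and idempotent.
    """
    # Sweep per chromosome over exon-union boundaries counting distinct
    # genes (a gene's own union intervals are disjoint, so interval events
    # count genes exactly once).
    events: dict[str, list[tuple[int, int]]] = {}
    for model in gene_models:
        for chrom, s, e, _ in model.exon_union:
            events.setdefault(chrom, []).append((s, 1))
            events[chrom].append((e, -1))
    masked_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        masked: list[tuple[int, int]] = []
        prev_pos: int | None = None
        for pos, delta in evs:
            if prev_pos is not None and pos > prev_pos and depth >= 2:
                if masked and masked[-1][1] == prev_pos:
                    masked[-1] = (masked[-1][0], pos)
                else:
                    masked.append((prev_pos, pos))
            depth += delta
            prev_pos = pos
        masked_by_chrom[chrom] = masked

    kept, dropped = [], []
    for model in gene_models:
        new_exons: list[tuple[str, int, int, str]] = []
        for chrom, s, e, strand in model.exon_union:
            for ns, ne in _subtract([(s, e)], masked_by_chrom.get(chrom, [])):
                new_exons.append((chrom, ns, ne, strand))
        if new_exons:
            kept.append(model.with_exons(new_exons))
        else:
            dropped.append(model.gene_id)
    return kept, dropped


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def read_intervals(
    observations: Iterable[AlignmentObservation],
    read_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Alignment intervals of (a subset of) aligned reads as a DataFrame."""
    rows = [
        (o.read_id, o.chrom, o.start, o.end)
        for o in observations
        if o.aligned and (read_ids is None or o.read_id in read_ids)
    ]
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end"])


def count_reads(
    reads: pd.DataFrame, gene_models: Sequence[GeneModel]
) -> pd.Series:
    """Count reads into masked exon unions (>= 1 bp overlap).

    ``reads`` needs columns read_id, chrom, start, end.  Each read is
    counted at most once: when it overlaps several genes the gene with
    the largest overlap wins, and an exact tie leaves the read uncounted.
    Returns integer counts indexed by gene id (all genes, zeros included).
    """
    if not gene_models:
        raise ValueError("no gene models loaded for this genome")
    trees: dict[str, IntervalTree] = {}
    for model in gene_models:
        for chrom, s, e, _ in model.exon_union:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, model.gene_id)

    counts = pd.Series(
        0, index=pd.Index([m.gene_id for m in gene_models], name="gene_id"), dtype=int
    )
    for chrom, start, end in zip(reads["chrom"], reads["start"], reads["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        overlap_bp: dict[str, int] = {}
        for iv in tree.overlap(start, end):
            bp = min(end, iv.end) - max(start, iv.begin)
            if bp > 0:
                overlap_bp[iv.data] = overlap_bp.get(iv.data, 0) + bp
        if not overlap_bp:
            continue
        best = max(overlap_bp.values())
        winners = [g for g, bp in overlap_bp.items() if bp == best]
        if len(winners) == 1:
            counts[winners[0]] += 1
    return counts


def rpkm(
    counts: pd.DataFrame | pd.Series,
    effective_length_bp: pd.Series,
    total_assigned_reads: pd.Series | float | None = None,
) -> pd.DataFrame | pd.Series:
    """Reads per kilobase of exon model per million assigned reads.

    ``total_assigned_reads`` defaults to the per-sample sum of gene
    counts (the species-assigned, gene-counted reads).  Samples with a
    zero total yield all-zero RPKM rather than a division error.
    """
    lengths = effective_length_bp.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:3]
        raise ValueError(f"no effective length for genes {missing}")
    if isinstance(counts, pd.Series):
        total = counts.sum() if total_assigned_reads is None else total_assigned_reads
        if total == 0:
            return counts * 0.0
        return counts / (lengths / 1e3) / (total / 1e6)
    totals = (
        counts.sum(axis=0)
        if total_assigned_reads is None
        else pd.Series(total_assigned_reads).reindex(counts.columns)
    )
    out = counts.div(lengths / 1e3, axis=0)
    safe = totals.replace(0, np.nan) / 1e6
    return out.div(safe, axis=1).fillna(0.0)


def detected_genes(
    counts: pd.DataFrame | pd.Series, cutoff: int = 1
) -> pd.DataFrame | pd.Series:
    """Boolean detection mask at the given read-count cutoff (default 1)."""
    return counts >= cutoff


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    matrix: pd.DataFrame,
    reference: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    M and A are computed directly on the expression values (the input is
    expected to be RPKM, which is already depth-normalized), pairwise
    against a reference sample, excluding genes with a zero in either
    sample.  M values outside the central (1 - 2*trim_m) rank band and A
    values outside the central (1 - 2*trim_a) band are trimmed; the
    remaining M are averaged with precision weights 1/(1/y + 1/y_ref).
    Factors are rescaled so their geometric mean is 1; the normalized
    value of sample s is value / factor_s.

    ``reference=None`` picks the sample whose upper quartile is closest
    to the mean upper quartile.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    values = matrix.to_numpy(dtype=float)
    col_sums = values.sum(axis=0)
    for sample, total in zip(matrix.columns, col_sums):
        if total == 0:
            raise ValueError(f"sample {sample!r} has all-zero expression")

    if reference is None:
        upper_quartiles = np.quantile(values, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(upper_quartiles - upper_quartiles.mean())))
    else:
        ref_idx = matrix.columns.get_loc(reference)

    ref = values[:, ref_idx]
    factors = np.ones(values.shape[1])
    for j in range(values.shape[1]):
        if j == ref_idx:
            continue
        both = (values[:, j] > 0) & (ref > 0)
        if not both.any():
            raise ValueError(
                f"samples {matrix.columns[j]!r} and {matrix.columns[ref_idx]!r} "
                "share no expressed genes"
            )
        y, r = values[both, j], ref[both]
        m = np.log2(y / r)
        a = 0.5 * np.log2(y * r)
        w = 1.0 / (1.0 / y + 1.0 / r)
        n = len(m)
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        keep = (
            (rank_m >= np.floor(n * trim_m) + 1)
            & (rank_m <= n - np.floor(n * trim_m))
            & (rank_a >= np.floor(n * trim_a) + 1)
            & (rank_a <= n - np.floor(n * trim_a))
        )
        if keep.any():
            factors[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        else:
            factors[j] = 2 ** np.average(m, weights=w)

    factors /= gmean(factors)
    return pd.Series(factors, index=matrix.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Assembled per-species expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression for one species.

    ``rpkm == 0`` exactly where ``counts == 0``; ``tmm_factor`` has
    geometric mean 1 across samples (None until >= 2 samples exist).
    """

    genome_id: str
    counts: pd.DataFrame
    rpkm: pd.DataFrame
    total_assigned_reads: pd.Series
    tmm_factor: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def normalized_rpkm(self) -> pd.DataFrame:
        if self.tmm_factor is None:
            return self.rpkm
        return self.rpkm.div(self.tmm_factor, axis=1)


def expression_matrix(
    counts_by_sample: Mapping[str, pd.Series],
    gene_models: Sequence[GeneModel],
    genome_id: str = "",
    normalize: bool = True,
) -> ExpressionMatrix:
    """Assemble counts from several samples into an ExpressionMatrix.

    Computes RPKM from the masked effective lengths and, when at least
    two samples are present and ``normalize`` is set, TMM factors on the
    RPKM values.
    """
    lengths = pd.Series(
        {m.gene_id: m.effective_length_bp for m in gene_models}, name="length"
    )
    counts = pd.DataFrame(dict(counts_by_sample)).reindex(lengths.index).fillna(0)
    counts = counts.astype(int)
    totals = counts.sum(axis=0)
    rpkm_values = rpkm(counts, lengths, totals)
    tmm = None
    if normalize and counts.shape[1] >= 2:
        tmm = tmm_factors(rpkm_values)
    return ExpressionMatrix(
        genome_id=genome_id,
        counts=counts,
        rpkm=rpkm_values,
        total_assigned_reads=totals,
        tmm_factor=tmm,
    )
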