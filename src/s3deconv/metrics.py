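"""Technical-performance metrics of the species separation.

These quantities characterise how much is lost and how much is wrong
when a mixed-species sample is split: the fraction of reads discarded as
species-ambiguous, the misassignment rate against known truth, read-loss
ratios, full/partial gene loss when shared reads are discarded, and the
rank correlation between a pure sample's expression and the same
species' expression recovered from a mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.stats import spearmanr

from .assignment import AMBIGUOUS, UNASSIGNED
from .io_formats import AlignmentObservation, GeneModel
from .quantify import count_reads, read_intervals


@dataclass
class SeparationMetrics:
    """Container for the separation quality numbers of one experiment."""

    n_reads: int
    ambiguous_fraction_aligned: float
    ambiguous_fraction_all: float
    assigned_fraction: float
    misassignment_rate: float | None = None
    n_misassigned: int | None = None
    n_genes_with_misassigned_reads: int | None = None
    read_loss_ratio: float | None = None
    full_loss_gene_fraction: float | None = None
    partial_loss_gene_fraction: float | None = None
    mix_spearman: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "n_reads": self.n_reads,
            "ambiguous_fraction_aligned": self.ambiguous_fraction_aligned,
            "ambiguous_fraction_all": self.ambiguous_fraction_all,
            "assigned_fraction": self.assigned_fraction,
        }
        for key in (
            "misassignment_rate",
            "n_misassigned",
            "n_genes_with_misassigned_reads",
            "read_loss_ratio",
            "full_loss_gene_fraction",
            "partial_loss_gene_fraction",
        ):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        if self.mix_spearman:
            out["mix_spearman"] = dict(self.mix_spearman)
        return out


def _is_assigned(labels: pd.Series) -> pd.Series:
    return ~labels.isin([AMBIGUOUS, UNASSIGNED])


def ambiguous_fraction(assignments: pd.DataFrame) -> dict[str, float]:
    """Species-ambiguous read fraction under both denominator conventions.

    ``aligned`` divides by reads aligned to at least one genome (the
    reads that had any chance of assignment); ``all_reads`` divides by
    every read in the sample.
    """
    n_ambiguous = int((assignments["label"] == AMBIGUOUS).sum())
    n_aligned = int((assignments["n_genomes_aligned"] > 0).sum())
    n_all = len(assignments)
    return {
        "aligned": n_ambiguous / n_aligned if n_aligned else 0.0,
        "all_reads": n_ambiguous / n_all if n_all else 0.0,
    }


def assigned_fraction(assignments: pd.DataFrame) -> float:
    """Fraction of all reads assigned to some species."""
    if len(assignments) == 0:
        return 0.0
    return float(_is_assigned(assignments["label"]).mean())


def read_loss_ratio(assignments: pd.DataFrame, origin_genome: str) -> float:
    """Ambiguity-driven read loss for a single-species sample.

    Ratio of reads discarded as ambiguous because they also map to the
    other species (cross-genome ambiguous reads) over reads that map to
    the genome of origin.
    """
    aligned_to_origin = assignments["aligned_in"].fillna("").str.split(",").map(
        lambda gs: origin_genome in gs
    )
    denom = int(aligned_to_origin.sum())
    cross_ambiguous = int(
        (
            (assignments["label"] == AMBIGUOUS)
            & (assignments["n_genomes_aligned"] >= 2)
        ).sum()
    )
    return cross_ambiguous / denom if denom else 0.0


def misassignment_rate(
    assignments: pd.DataFrame, truth_labels: pd.Series | pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Fraction of species-assigned reads assigned to the wrong genome.

    ``truth_labels`` maps read_id to the genome of origin (a Series
    indexed by read_id, or a DataFrame with read_id and genome_id
    columns).  Returns (rate, table of misassigned reads); the rate is 0
    when no reads were assigned at all.
    """
    if isinstance(truth_labels, pd.DataFrame):
        truth_labels = truth_labels.set_index("read_id")["genome_id"]
    assigned = assignments[_is_assigned(assignments["label"])]
    if assigned.empty:
        return 0.0, assigned.copy()
    truth = truth_labels.reindex(assigned["read_id"])
    if truth.isna().any():
        missing = truth[truth.isna()].index.tolist()[:3]
        raise ValueError(f"truth labels missing for reads {missing}")
    wrong = assigned[assigned["label"].to_numpy() != truth.to_numpy()]
    return len(wrong) / len(assigned), wrong.copy()


def misassigned_gene_tally(
    wrong: pd.DataFrame,
    observations: Sequence[AlignmentObservation],
    gene_models_by_genome: dict[str, Sequence[GeneModel]],
) -> int:
    """Number of wrong-genome genes receiving at least one misassigned read."""
    total = 0
    obs_list = list(observations)
    for genome_id, models in gene_models_by_genome.items():
        read_ids = set(wrong.loc[wrong["label"] == genome_id, "read_id"])
        if not read_ids or not models:
            continue
        intervals = read_intervals(
            (o for o in obs_list if o.genome_id == genome_id), read_ids
        )
        counts = count_reads(intervals, models)
        total += int((counts > 0).sum())
    return total


def gene_loss(
    counts_keep_shared: pd.Series, counts_discard_shared: pd.Series
) -> tuple[float, float]:
    """Full and partial gene-loss fractions caused by discarding shared reads.

    ``counts_keep_shared`` quantifies with ambiguous reads retained
    (uniqueness-only filter); ``counts_discard_shared`` after the full
    species filter.  Denominator: genes expressed (non-zero) before the
    filter.  Full loss: expression drops to zero; partial loss: fewer
    reads but still non-zero.  The categories are disjoint.
    """
    keep = counts_keep_shared
    discard = counts_discard_shared.reindex(keep.index).fillna(0)
    expressed = keep > 0
    n_expressed = int(expressed.sum())
    if n_expressed == 0:
        return 0.0, 0.0
    full = int((expressed & (discard == 0)).sum())
    partial = int((expressed & (discard > 0) & (discard < keep)).sum())
    return full / n_expressed, partial / n_expressed


def mix_fidelity(
    pure_expression: pd.Series, separated_expression: pd.Series
) -> float:
    """Spearman rho between pure-sample and mixed-then-separated expression.

    Computed over genes detected (non-zero) in either vector, so that a
    block of genes silent in both cannot dominate the rank correlation.
    Ties are mid-ranked.
    """
    separated = separated_expression.reindex(pure_expression.index).fillna(0.0)
    detected = (pure_expression > 0) | (separated > 0)
    if detected.sum() < 2:
        raise ValueError("fewer than two detected genes; correlation undefined")
    rho, _ = spearmanr(pure_expression[detected], separated[detected])
    return float(rho)


def separation_metrics(
    assignments: pd.DataFrame,
    truth_labels: pd.Series | pd.DataFrame | None = None,
) -> SeparationMetrics:
    """Bundle the read-level metrics for one assignment table."""
    frac = ambiguous_fraction(assignments)
    result = SeparationMetrics(
        n_reads=len(assignments),
        ambiguous_fraction_aligned=frac["aligned"],
        ambiguous_fraction_all=frac["all_reads"],
        assigned_fraction=assigned_fraction(assignments),
    )
    if truth_labels is not None:
        rate, wrong = misassignment_rate(assignments, truth_labels)
        result.misassignment_rate = rate
        result.n_misassigned = len(wrong)
    return result
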