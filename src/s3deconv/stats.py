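"""Downstream statistics: fold changes, permutation DE test, overlap test.

Differential expression uses the moderated t-like statistic from
significance analysis of microarrays (SAM), d = (mean1 - mean2)/(s + s0),
with p-values from sample-label permutations pooled across genes into a
global null, and Benjamini-Hochberg FDR.  Fold changes add a pseudo-value
of 0.3 RPKM (a background-expression floor) to both means before taking
the ratio, which keeps ratios finite and shrinks them for genes near the
detection limit.  Gene-list overlaps are tested with a one-sided
(enrichment) hypergeometric tail, i.e. Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDO_RPKM = 0.3

S0_RULES = ("median_s", "percentile5")


@dataclass(frozen=True)
class OverlapTest:
    """Result of a gene-list overlap test against a finite universe."""

    k_overlap: int
    n1: int
    n2: int
    N_universe: int
    p_value: float


@dataclass
class PermutationResult:
    """Per-gene permutation p-values plus how the null was built."""

    p_values: pd.Series
    d_observed: pd.Series
    s0: float
    n_splits: int
    n_null: int
    exhaustive: bool


def fold_change(x, y, pseudo: float = DEFAULT_PSEUDO_RPKM):
    """(x + pseudo) / (y + pseudo); symmetric: fc(x,y) * fc(y,x) == 1."""
    return (np.asarray(x, dtype=float) + pseudo) / (np.asarray(y, dtype=float) + pseudo)


def _pooled_se(group1: np.ndarray, group2: np.ndarray) -> float:
    n1, n2 = len(group1), len(group2)
    ss = ((group1 - group1.mean()) ** 2).sum() + ((group2 - group2.mean()) ** 2).sum()
    pooled_var = ss / (n1 + n2 - 2)
    return float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))


def sam_statistic(group1, group2, s0: float = 0.0) -> float:
    """SAM's moderated statistic d = (mean1 - mean2) / (s + s0).

    ``s`` is the pooled standard error of the mean difference.  The
    fudge factor ``s0`` stabilises d for genes with tiny variance.
    """
    group1 = np.asarray(group1, dtype=float)
    group2 = np.asarray(group2, dtype=float)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("sam_statistic needs >= 2 values per group")
    s = _pooled_se(group1, group2)
    if s + s0 == 0:
        raise ValueError("zero variance in both groups and s0 = 0")
    return float((group1.mean() - group2.mean()) / (s + s0))


def _d_for_split(
    values: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float
) -> np.ndarray:
    """Vectorized per-gene d statistic for one sample split."""
    g1, g2 = values[:, idx1], values[:, idx2]
    n1, n2 = g1.shape[1], g2.shape[1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    ss = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return d


def _two_groups(labels) -> tuple[np.ndarray, np.ndarray, list]:
    labels = pd.Series(list(labels))
    uniq = labels.unique().tolist()
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    idx1 = np.flatnonzero((labels == uniq[0]).to_numpy())
    idx2 = np.flatnonzero((labels == uniq[1]).to_numpy())
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("one group is empty")
    return idx1, idx2, uniq


def _enumerate_splits(n: int, n1: int) -> list[np.ndarray]:
    """All distinct group-1 index sets; complements deduplicated for n1 == n2."""
    splits = []
    for combo in combinations(range(n), n1):
        if 2 * n1 == n and 0 not in combo:
            continue  # the complement split yields the same |d|
        splits.append(np.array(combo, dtype=int))
    return splits


def permutation_test(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    s0: float | None = None,
    s0_rule: str = "median_s",
    seed: int = 0,
) -> PermutationResult:
    """SAM-style permutation p-values with a null pooled across genes.

    For every permutation of the sample labels the per-gene |d*| values
    of ALL genes enter one global null distribution; a gene's p-value is
    (1 + #{null |d*| >= |d_observed|}) / (1 + null size), which keeps
    p-values valid (never below the additive smoothing floor).  When the
    number of distinct label splits is <= ``n_perm`` they are enumerated
    exhaustively (complementary splits counted once); otherwise
    ``n_perm`` random permutations are drawn with the given seed.

    ``s0`` defaults to the ``s0_rule`` summary (median or 5th percentile)
    of the per-gene pooled standard errors under the observed grouping.
    """
    if matrix.shape[1] != len(list(labels)):
        raise ValueError("labels must match the matrix columns")
    idx1, idx2, _ = _two_groups(labels)
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("permutation test needs >= 2 samples per group")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[1]
    n1 = len(idx1)

    # per-gene pooled SE under the observed grouping, for the fudge factor
    g1, g2 = values[:, idx1], values[:, idx2]
    ss = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (g2 - g2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_per_gene = np.sqrt(ss / (n1 + len(idx2) - 2) * (1.0 / n1 + 1.0 / len(idx2)))
    if s0 is None:
        if s0_rule == "median_s":
            s0 = float(np.median(s_per_gene))
        elif s0_rule == "percentile5":
            s0 = float(np.percentile(s_per_gene, 5))
        else:
            raise ValueError(f"unknown s0 rule {s0_rule!r}")

    d_obs = _d_for_split(values, idx1, idx2, s0)

    n_distinct = comb(n, n1) // (2 if 2 * n1 == n else 1)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        splits = _enumerate_splits(n, n1)
    else:
        rng = np.random.default_rng(seed)
        splits = []
        for _ in range(n_perm):
            perm = rng.permutation(n)
            splits.append(np.sort(perm[:n1]))

    null: list[np.ndarray] = []
    all_idx = np.arange(n)
    for split in splits:
        other = np.setdiff1d(all_idx, split, assume_unique=True)
        null.append(np.abs(_d_for_split(values, split, other, s0)))
    null_sorted = np.sort(np.concatenate(null))
    n_null = len(null_sorted)

    exceed = n_null - np.searchsorted(null_sorted, np.abs(d_obs), side="left")
    p = (1.0 + exceed) / (1.0 + n_null)
    return PermutationResult(
        p_values=pd.Series(p, index=matrix.index, name="p_value"),
        d_observed=pd.Series(d_obs, index=matrix.index, name="d"),
        s0=float(s0),
        n_splits=len(splits),
        n_null=n_null,
        exhaustive=exhaustive,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, mapped back to the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_overlap(k: int, n1: int, n2: int, N: int) -> OverlapTest:
    """One-sided (enrichment) Fisher's exact test for a gene-list overlap.

    p = P(X >= k) where X ~ Hypergeometric(N, n1, n2): the chance that two
    random lists of sizes n1 and n2 drawn from a universe of N genes share
    at least k members.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("list sizes must lie within the universe")
    if not (0 <= k <= min(n1, n2)):
        raise ValueError("overlap must be within 0..min(n1, n2)")
    if k == 0:
        # the event X >= 0 is the entire support (and N = 0 would make
        # the hypergeometric survival function degenerate)
        return OverlapTest(k_overlap=k, n1=n1, n2=n2, N_universe=N, p_value=1.0)
    p = float(hypergeom.sf(k - 1, N, n1, n2))
    return OverlapTest(k_overlap=k, n1=n1, n2=n2, N_universe=N, p_value=min(p, 1.0))


def differential_expression(
    matrix: pd.DataFrame,
    labels,
    pseudo: float = DEFAULT_PSEUDO_RPKM,
    n_perm: int = 1000,
    s0: float | None = None,
    s0_rule: str = "median_s",
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-gene DE table: means, pseudo-count fold change, d, p, FDR."""
    idx1, idx2, _ = _two_groups(labels)
    values = matrix.to_numpy(dtype=float)
    mean1 = values[:, idx1].mean(axis=1)
    mean2 = values[:, idx2].mean(axis=1)
    perm = permutation_test(
        matrix, labels, n_perm=n_perm, s0=s0, s0_rule=s0_rule, seed=seed
    )
    table = pd.DataFrame(
        {
            "mean_group1": mean1,
            "mean_group2": mean2,
            "fold_change": fold_change(mean1, mean2, pseudo),
            "d_statistic": perm.d_observed,
            "p_value": perm.p_values,
            "fdr": bh_fdr(perm.p_values.to_numpy()),
        },
        index=matrix.index,
    )
    table.index.name = "gene_id"
    return table


def de_genes(
    matrix: pd.DataFrame,
    labels,
    fc_cutoff: float = 2.0,
    fdr_cutoff: float = 0.05,
    mode: str = "fc",
    direction: str = "both",
    pseudo: float = DEFAULT_PSEUDO_RPKM,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Select differentially expressed genes by fold change or FDR.

    ``mode='fc'`` keeps detected genes (non-zero somewhere) whose
    pseudo-count fold change exceeds ``fc_cutoff`` (direction 'up'),
    falls below 1/``fc_cutoff`` ('down') or either ('both') — the
    fold-change cut-off is the right choice when the group sizes are
    unbalanced.  ``mode='fdr'`` keeps genes with permutation FDR below
    ``fdr_cutoff``.  Returns (sorted gene list, full DE table).
    """
    if mode not in ("fc", "fdr"):
        raise ValueError(f"unknown mode {mode!r}")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if matrix.empty:
        return [], pd.DataFrame(
            columns=["mean_group1", "mean_group2", "fold_change"]
        )
    idx1, idx2, _ = _two_groups(labels)
    values = matrix.to_numpy(dtype=float)
    mean1 = values[:, idx1].mean(axis=1)
    mean2 = values[:, idx2].mean(axis=1)
    if mode == "fc":
        table = pd.DataFrame(
            {
                "mean_group1": mean1,
                "mean_group2": mean2,
                "fold_change": fold_change(mean1, mean2, pseudo),
            },
            index=matrix.index,
        )
        detected = (values > 0).any(axis=1)
        up = table["fold_change"] > fc_cutoff
        down = table["fold_change"] < 1.0 / fc_cutoff
        if direction == "up":
            selected = up
        elif direction == "down":
            selected = down
        else:
            selected = up | down
        genes = sorted(table.index[detected & selected])
        return genes, table
    table = differential_expression(
        matrix, labels, pseudo=pseudo, n_perm=n_perm, seed=seed
    )
    genes = sorted(table.index[table["fdr"] < fdr_cutoff])
    return genes, table
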