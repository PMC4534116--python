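"""Independent reference implementations used only to check the package.

Each oracle is a deliberately naive, literal restatement of the rule it
verifies — brute-force scans, exhaustive enumerations and direct formula
transcriptions — sharing no code with the implementation under test.
"""

from __future__ import annotations

from math import comb

import numpy as np


# --- species-assignment truth table ---------------------------------------

def classify_oracle(state_a, state_b, mu, ms, d, strict):
    """Literal truth table of the read-classification rules.

    ``state_a``/``state_b``: None (unaligned) or (unique: bool, m: int).
    Returns (label, reason) with labels 'A', 'B', 'ambiguous', 'unassigned'.
    """
    if state_a is None and state_b is None:
        return ("unassigned", "unaligned")
    if state_a is None or state_b is None:
        label = "A" if state_b is None else "B"
        unique, m = state_a if state_b is None else state_b
        if not unique:
            return ("ambiguous", "not_unique")
        if m <= mu:
            return (label, "unique_only")
        return ("unassigned", "too_many_mismatches")
    if strict:
        return ("ambiguous", "shared_tie")
    (unique_a, m_a), (unique_b, m_b) = state_a, state_b
    if m_a == m_b:
        return ("ambiguous", "shared_tie")
    if m_a < m_b:
        winner, w_unique, w_m, l_m = "A", unique_a, m_a, m_b
    else:
        winner, w_unique, w_m, l_m = "B", unique_b, m_b, m_a
    if l_m - w_m >= d:
        if not w_unique:
            return ("ambiguous", "not_unique")
        if w_m <= ms:
            return (winner, "rescued_by_difference")
    return ("ambiguous", "shared_tie")


# --- alignment -------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_best_placements(read: str, genome: str, max_mismatch: int):
    """Full O(L*k) scan of both strands; best (pos, strand, mm) tuples."""
    k = len(read)
    probes = (("+", read), ("-", revcomp_str(read)))
    hits = []
    for pos in range(len(genome) - k + 1):
        window = genome[pos : pos + k]
        for strand, probe in probes:
            mm = sum(a != b for a, b in zip(window, probe))
            if mm <= max_mismatch:
                hits.append((pos, strand, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return sorted((h for h in hits if h[2] == best), key=lambda h: (h[1], h[0]))


# --- quantification --------------------------------------------------------

def brute_force_counts(reads, gene_exons):
    """Count reads into genes by literal bp-set intersection.

    ``reads``: iterable of (read_id, chrom, start, end); ``gene_exons``:
    dict gene_id -> list of (chrom, start, end).  Largest-overlap gene
    wins, exact ties count nowhere.
    """
    counts = {g: 0 for g in gene_exons}
    base_sets = {
        g: {(c, p) for c, s, e in exons for p in range(s, e)}
        for g, exons in gene_exons.items()
    }
    for _, chrom, start, end in reads:
        read_set = {(chrom, p) for p in range(start, end)}
        overlaps = {
            g: len(read_set & bases) for g, bases in base_sets.items()
        }
        overlaps = {g: n for g, n in overlaps.items() if n > 0}
        if not overlaps:
            continue
        best = max(overlaps.values())
        winners = [g for g, n in overlaps.items() if n == best]
        if len(winners) == 1:
            counts[winners[0]] += 1
    return counts


def brute_force_tmm(matrix: np.ndarray, ref: int, trim_m=0.3, trim_a=0.05):
    """Direct transcription of the trimmed weighted-mean-of-M formula.

    Returns raw per-sample factors relative to ``ref`` (no geometric-mean
    rescale).  M and A on the values themselves, pairwise-zero exclusion,
    rank-band trimming on both M and A, precision weights 1/(1/y+1/r).
    """
    n_samples = matrix.shape[1]
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        y = matrix[:, j]
        r = matrix[:, ref]
        ok = (y > 0) & (r > 0)
        y, r = y[ok], r[ok]
        m = np.log2(y / r)
        a = 0.5 * np.log2(y * r)
        w = 1.0 / (1.0 / y + 1.0 / r)
        n = len(m)
        import scipy.stats

        rm = scipy.stats.rankdata(m)
        ra = scipy.stats.rankdata(a)
        keep = (
            (rm >= np.floor(n * trim_m) + 1)
            & (rm <= n - np.floor(n * trim_m))
            & (ra >= np.floor(n * trim_a) + 1)
            & (ra <= n - np.floor(n * trim_a))
        )
        if keep.any():
            factors[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        else:
            factors[j] = 2 ** (np.sum(w * m) / np.sum(w))
    return factors


# --- statistics ------------------------------------------------------------

def hypergeom_tail_exact(k: int, N: int, n1: int, n2: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n1, n2) by exact pmf summation."""
    denom = comb(N, n2)
    total = 0
    for j in range(k, min(n1, n2) + 1):
        if n2 - j > N - n1:
            continue
        total += comb(n1, j) * comb(N - n1, n2 - j)
    return total / denom


def bh_stepup(p_values):
    """Hand transcription of the Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rank_then_pearson(x, y):
    """Spearman rho as Pearson correlation of mid-ranked values."""
    import scipy.stats

    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def sam_d_direct(g1, g2, s0):
    """d = (mean1-mean2)/(s+s0) with s the pooled SE, written out longhand."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    n1, n2 = len(g1), len(g2)
    sp2 = (np.sum((g1 - g1.mean()) ** 2) + np.sum((g2 - g2.mean()) ** 2)) / (
        n1 + n2 - 2
    )
    s = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return (g1.mean() - g2.mean()) / (s + s0)
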