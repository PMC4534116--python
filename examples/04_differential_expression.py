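"""Differential expression and gene-list overlap testing.

Spikes a four-fold effect into 10 % of 200 genes across two groups of
four replicates, tests with the SAM-statistic permutation test (FDR
mode) and the
pseudo-count fold-change cutoff (fc mode), then asks whether the two
resulting gene lists overlap more than chance with Fisher's exact test
over a 24,112-gene universe.
"""

import numpy as np
import pandas as pd

from s3deconv import de_genes, fisher_overlap

rng = np.random.default_rng(4)
n_genes = 200
base = rng.lognormal(1.0, 1.0, n_genes)
spiked = set(rng.choice(n_genes, n_genes // 10, replace=False))
effect = np.array([4.0 if i in spiked else 1.0 for i in range(n_genes)])

matrix = pd.DataFrame(
    {
        **{f"t{i}": base * effect * rng.lognormal(0, 0.3, n_genes) for i in range(4)},
        **{f"c{i}": base * rng.lognormal(0, 0.3, n_genes) for i in range(4)},
    },
    index=[f"g{i}" for i in range(n_genes)],
)
labels = ["treated"] * 4 + ["control"] * 4

fc_genes, fc_table = de_genes(matrix, labels, mode="fc", fc_cutoff=2.0,
                              direction="up")
fdr_genes, fdr_table = de_genes(matrix, labels, mode="fdr", fdr_cutoff=0.05,
                                seed=0)
truth = {f"g{i}" for i in spiked}
print(f"spiked genes: {len(truth)}")
print(f"fold-change mode (>2x, pseudo 0.3): {len(fc_genes)} genes, "
      f"{len(set(fc_genes) & truth)} true")
print(f"FDR mode (SAM permutation, <5 %):   {len(fdr_genes)} genes, "
      f"{len(set(fdr_genes) & truth)} true")

test = fisher_overlap(
    k=len(set(fc_genes) & set(fdr_genes)),
    n1=len(fc_genes),
    n2=len(fdr_genes),
    N=24_112,
)
print(f"\nlist overlap: {test.k_overlap} of {test.n1} vs {test.n2} genes, "
      f"universe {test.N_universe}: p = {test.p_value:.3g}")
print(
    "\nThe fold-change cutoff is preferred when group sizes are unbalanced; "
    "the permutation FDR is the calibrated (more conservative) alternative "
    "for balanced designs.  The tiny overlap p-value says the two "
    "selections agree far beyond chance."
)
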