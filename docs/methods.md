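# Methods

## The separation model

`s3deconv` separates a mixed two-species RNA-seq sample (typically a
human tumor xenografted into mouse, or a human/mouse co-culture) into
per-species expression profiles without physically sorting the cells.
Every read is aligned independently to both reference genomes; the
per-read evidence within one genome is collapsed to an
`AlignmentObservation` — whether it aligned, whether the alignment was
unique (one co-optimal locus; the MAPQ-255 convention of spliced
aligners, or `NH == 1`), and the best alignment's edit distance (`NM`
tag).

Classification uses three thresholds:

* **Mu** — maximum mismatches for a read seen in only one genome
  (default 1);
* **Ms** — maximum mismatches, in the winning genome, for a read seen
  in both (default 1);
* **D** — minimum mismatch-count advantage the winning genome must have
  over every other aligned genome to rescue a shared read (default 2).

The decision procedure per read: unaligned everywhere → *unassigned*;
aligned (uniquely) in exactly one genome → that species if `m ≤ Mu`,
else unassigned; aligned in several genomes → the genome with strictly
fewest mismatches wins only if it beats every other by `≥ D`, is unique
and has `m ≤ Ms`, otherwise the read is *species-ambiguous* and
discarded.  A read that aligns only non-uniquely can never be assigned;
a non-unique alignment in a losing genome still counts as cross-species
evidence.  `strict` mode disables the difference rescue entirely and is
exactly equivalent to an unreachably large `D`.  Three-genome mode only
changes "the other genome" to "every other genome".

Two conventions are worth making explicit.  A shared read whose winner
is decisive but exceeds `Ms` is recorded as ambiguous (species
conflict), while a single-genome read exceeding `Mu` is unassigned
(quality loss); the ambiguous-fraction metric therefore counts only
species conflicts.  Because aligners disagree on what a "mismatch" is,
the mismatch count is taken from `NM` as-is (edit distance including
indels); with the built-in ungapped simulator the two notions coincide.

## Quantification

Counting follows the exon-union model: all isoforms of a gene are
merged into disjoint intervals, any base pair claimed by two or more
distinct gene ids is masked out of all of them (genes left empty are
dropped and reported), and a read is counted to the gene whose masked
union it overlaps most, with a 1-bp minimum overlap — a read hanging
over a gene end still counts in full.  A read tied between two genes is
counted to neither (deterministic and rare).  microRNA and snoRNA genes
are removed before counting: by annotation biotype when available,
otherwise by symbol (`MIR`/`MIRLET`/`SNOR` followed by a digit, an
optional snoRNA class letter D/A, or `LET`; plain words like
"MIRROR-like" survive).  RPKM is
`count / (effective_length/1e3) / (total_assigned/1e6)` with the
per-sample total being the species-assigned, gene-counted reads.
Detection is `count ≥ 1`.

TMM factors are computed **on the RPKM values** (not raw counts): M and
A values are taken directly on the expression values, pairwise against
a reference sample (the one whose upper quartile is closest to the mean
upper quartile), excluding genes zero in either sample; M is trimmed
30 % per tail and A 5 % per tail by rank; the surviving M are averaged
with precision weights `1/(1/y + 1/y_ref)` and factors are rescaled to
geometric mean 1.  Because RPKM is already depth-normalized, no
library-size division enters M — this is also what makes a globally
doubled sample come out with factors `(1/√2, √2)` rather than `(1, 1)`.

## Statistics

Fold changes add a pseudo-value of 0.3 RPKM (a background-expression
floor) to both means before the ratio, which keeps ratios finite and
shrinks them near the detection limit.  Differential expression uses
the SAM statistic `d = (mean₁ − mean₂)/(s + s₀)` with `s` the pooled
standard error of the mean difference and `s₀` a fudge factor
(default: the median of the per-gene `s`; a 5th-percentile rule is also
offered — the exact `s₀` is a free parameter of the method).  P-values
come from permuting sample labels with the per-gene `|d*|` of **all**
genes pooled into one global null; `p = (1 + #{|d*| ≥ |d|})/(1 + n_null)`,
which enforces validity (p never below the smoothing floor).  When the
number of distinct label splits is small (e.g. 3 for a 2 v 2 design,
complementary splits counted once) they are enumerated exhaustively
instead of sampled, eliminating Monte-Carlo noise at the small group
sizes typical of these experiments.  FDR is Benjamini–Hochberg.  Gene
lists can be selected either by pseudo-count fold change (the right
choice when group sizes are unbalanced) or by FDR.  Gene-list overlaps
are tested one-sided (enrichment) with the hypergeometric tail, i.e.
Fisher's exact test, against a finite gene universe (for real
human/mouse annotations ~24,112 and ~23,225 genes respectively).

## The simulator and what it does (not) emulate

The simulator builds an i.i.d. random "human" genome (default 80 kb,
100 genes, 1–3 exons of 120–300 bp each), derives the "mouse" genome by
i.i.d. substitutions at a per-bp **divergence** rate with identical
gene coordinates (perfect orthologs; optionally a third "rat" genome),
draws reads from exon-interior positions of genes chosen by fixed
lognormal(0, 1) expression weights, and injects substitution errors.
Defaults: divergence 0.10 (the order of human–mouse exonic sequence
divergence), error rate 0.005/bp, 50-bp single-end reads, 20,000 reads
per species.  The mixed sample is the concatenation of the two pure
samples, mirroring how real samples are mixed in silico.

The oracle aligner is exhaustive for ungapped placements within
`max_mismatch` (default 10) substitutions on either strand: a
pigeonhole seed search (mismatch budgets 4 → 7 → 10, with `budget+1`
disjoint seeds each) whose passes are provably complete up to their
budget, verified against a naive full scan in the tests.  It emits all
co-optimal placements with `NM`/`NH` tags and MAPQ 255 for unique hits.

Deliberate idealizations, and hence what passing tests do and do not
show about real data: substitutions only (no indels, so `NM` equals the
mismatch count exactly); no junction-spanning reads (the aligner is
unspliced); uniform divergence along the genome; constant base quality.
Real genomes have heterogeneous conservation — ambiguous reads
concentrate in conserved genes — while the simulator spreads ambiguity
uniformly, so at deep per-gene coverage almost every simulated gene
loses *some* reads (a high "partial loss" fraction) even though full
loss and misassignment match the real method's behaviour.  Tests
demonstrate the correctness of the decision procedure, counting and
statistics, and the qualitative separation regime (low misassignment,
modest read loss, faithful expression recovery), not genome-scale
loss percentages.

## Numerical choices and scales

* Internal coordinates are 0-based half-open everywhere; GTF (1-based
  closed) and SAM text are converted at the parse boundary only.
* Multimapper collapse keeps the minimum `NM`; ties on location are
  broken by (chromosome, position, strand) for determinism.
* All randomness flows through `numpy` Generators seeded from explicit
  integers; fixtures are byte-reproducible (SHA-256 manifests).
* Simulation sizes used by the test-suite and the acceptance script
  (30–80 kb genomes, 1,500–50,000 reads per species) were chosen so a
  complete run, including the exhaustive aligner, executes in well
  under a minute per scenario on one CPU; the separation regime is
  insensitive to genome size once a few thousand reads per gene-set are
  drawn.
* At low divergence the assignable fraction is bounded by sequence
  information, not implementation: a 50-bp read window contains no
  divergent site with probability `(1−δ)^50` (0.61 at δ = 0.01) and a
  rescue at `D = 2` needs at least two sites, so only
  `1 − (1−δ)^50 − 50δ(1−δ)^49` ≈ 9 % of reads are assignable at
  δ = 0.01, versus ≈ 93 % at the default δ = 0.10.

## Known limitations

Paired-end mate reconciliation, CRAM, isoform-level quantification,
EM-based multimapper rescue and k-mer (alignment-free) species sorting
are out of scope.  TMM-on-RPKM is unconventional (edgeR applies TMM to
counts with library sizes) but is implemented as specified for this
pipeline; use `tmm_factors` on a count matrix at your own discretion.
The `-bothendsceil`-style 1-bp-overlap full-count rule is a stated
approximation of exon-boundary handling in established RPKM scripts.
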