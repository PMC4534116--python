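"""From species-assigned reads to normalized expression.

Counts two samples' reads into masked exon unions, converts to RPKM
(reads per kilobase of exon model per million assigned reads) and
balances the samples with TMM (trimmed mean of M-values) factors.
"""

from s3deconv import assign_all, AssignmentParams
from s3deconv.quantify import (
    count_reads,
    expression_matrix,
    filter_small_rna,
    mask_name_overlaps,
    read_intervals,
)
from s3deconv.simulate import (
    SimulationConfig,
    align_observations,
    simulate_genomes,
    simulate_reads,
)

config = SimulationConfig(genome_length_bp=30_000, n_genes=30, n_reads=2_000, seed=3)
experiment = simulate_genomes(config)

models = experiment.gene_models["human"]
models, removed = filter_small_rna(models)  # drop miRNA/snoRNA genes
models, fully_masked = mask_name_overlaps(models)  # drop multi-gene bp

counts_by_sample = {}
for sample in ("rep1", "rep2"):
    seed = {"rep1": 21, "rep2": 22}[sample]
    reads, _ = simulate_reads(experiment, sample, genome_id="human", seed=seed)
    observations = {
        g: align_observations(reads, experiment.sequences[g], g)
        for g in config.genome_ids
    }
    table, _ = assign_all(observations, AssignmentParams())
    assigned = set(table.loc[table["label"] == "human", "read_id"])
    counts_by_sample[sample] = count_reads(
        read_intervals(observations["human"], assigned), models
    )

expr = expression_matrix(counts_by_sample, models, genome_id="human")
print("assigned reads per sample:", expr.total_assigned_reads.to_dict())
print("TMM factors:", expr.tmm_factor.round(4).to_dict())
print("\nfirst genes (RPKM, TMM-normalized):")
print(expr.normalized_rpkm().head(5).round(2).to_string())
print(
    "\nRPKM divides counts by gene length (kb) and library size (millions); "
    "the TMM factors (geometric mean 1) remove residual composition bias "
    "between the samples, so a gene's normalized values are comparable "
    "across columns."
)
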