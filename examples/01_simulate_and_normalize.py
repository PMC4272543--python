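"""Generate a synthetic storage trial and normalize it to RPKM.

The generator emulates a postharvest experiment: per cortex tissue,
4 fruit sampled at harvest and 16 after storage, with half of the
stored fruit developing browning.  Counts are negative-binomial with
50 planted browning genes and 50 planted ripening genes.
"""

from pomebrown import (
    SimConfig,
    classify_samples,
    compute_rpkm,
    expressed_gene_counts,
    generate_experiment,
)

counts, genes, samples, truth = generate_experiment(SimConfig(seed=1))
print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")

expr = compute_rpkm(counts, genes, samples)
expressed = expressed_gene_counts(expr, min_rpkm=0.0)
print(
    f"expressed genes per sample: {expressed.mean():.0f} ± {expressed.std(ddof=1):.0f}"
    " (genes with at least one mapped read)"
)

samples = classify_samples(samples, bi_cutoff=3.0)
print("\nsamples per tissue/class (browning index > 3 means affected):")
print(samples.table.groupby(["tissue", "class"]).size())
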