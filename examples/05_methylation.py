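"""Feature-level methylation analysis and genotype comparison.

Simulates per-cytosine bisulfite reports for wild type and a
hypomethylated mutant (all true rates scaled by 0.6), estimates the
bisulfite conversion rate from the unmethylated control contig, applies
the inclusive >= 5% methylated-cytosine rule, aggregates over gene bodies,
500 bp upstream windows and repeats, and compares genotypes by t-test.
"""

import chromdev as cd

config = cd.SimulationConfig(seed=13, n_repeats=200, intergenic_extra_max=2600)
annotation = cd.build_genome(config)
index = cd.assign_feature_classes(annotation, upstream_len=config.upstream_len)

for genotype in ("wt", "mutant"):
    records, _ = cd.simulate_cytosine_report(annotation, config, genotype)
    rate = cd.estimate_conversion_rate(records, annotation.control_contig)
    print(f"{genotype:6s} conversion rate: {rate:.1f}% "
          f"(simulated {100 * config.conversion_probability:.1f}%)")

comparison = cd.methylation_comparison_pipeline(config)
print(f"{'class':10s} {'wt median':>10s} {'mut median':>10s} {'diff':>7s} {'p':>9s}")
for cls, c in comparison.by_class.items():
    print(
        f"{cls:10s} {c.wt.median:10.1f} {c.mutant.median:10.1f} "
        f"{c.mean_difference:+7.1f} {c.p_value:9.2g}"
    )
# Repeats are the most methylated compartment, the mutant is below the wild
# type in every feature class, and the conversion-rate QC recovers the
# simulated value — the pattern the pipeline is built to quantify.
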