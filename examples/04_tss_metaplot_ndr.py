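"""TSS metaplots and nucleosome-depleted-region (NDR) metrics.

Simulates MNase data in which strongly expressed genes carry a wider NDR
upstream of the TSS (300 bp) than weakly expressed genes (120 bp),
computes per-gene max-normalised occupancy metaplots around TSSs, and
measures the NDR minimum and width per class.
"""

import chromdev as cd

config = cd.isolated_array_config(seed=5, n_genes=300)
annotation = cd.build_genome(config)
classes = {
    g.gene_id: ("high" if i % 2 else "low") for i, g in enumerate(annotation.genes)
}
metaplot = cd.tss_metaplot_pipeline(config, classes=classes)

print("genes per class:", metaplot.n_genes, "| excluded:", metaplot.n_excluded)
for label in ("low", "high"):
    m = cd.ndr_metrics(metaplot, label)
    true_width = config.ndr_width(label)
    print(
        f"{label:5s} NDR minimum at {m.min_pos:+6.0f} bp, "
        f"width {m.width:4.0f} bp (simulated {true_width} bp)"
    )
# The class-average minimum sits just upstream of the TSS and the measured
# widths reproduce the simulated ordering: larger NDRs at strongly
# expressed genes.
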