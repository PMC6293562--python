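"""End-to-end convenience pipelines chaining the simulator and analyses.

Each function runs one complete workflow from a :class:`SimulationConfig`
(or pre-built inputs) to the analysis result. They exist so scripts, tests
and examples exercise exactly the same code paths.
"""

from __future__ import annotations

from .expression import classify_by_wt_rpkm, compute_rpkm
from .methylation import (
    GenotypeComparison,
    aggregate_by_feature,
    call_methylated,
    compare_genotypes,
    estimate_conversion_rate,
)
from .io import assign_feature_classes
from .nucleosomes import (
    CallerParams,
    DistanceHistogram,
    MetaplotMatrix,
    NucleosomeCall,
    adjacent_distances,
    call_nucleosomes,
    occupancy_from_fragments,
    smooth_track,
    tss_metaplot,
)
from .records import FragmentRecord, GenomeAnnotation
from .simulate import (
    SimulationConfig,
    build_genome,
    expression_classes_from_truth,
    simulate_counts,
    simulate_cytosine_report,
    simulate_mnase_fragments,
)


def isolated_array_config(seed: int, n_genes: int = 520) -> SimulationConfig:
    """A genome layout whose phased arrays do not collide between genes.

    Intergenic spacing exceeds the upstream-array extent, so each gene's
    true dyads stand alone — the setting for caller-recovery and spacing
    analyses over well-defined arrays.
    """
    return SimulationConfig(
        seed=seed,
        n_contigs=8,
        n_genes=n_genes,
        contig_length=400_000,
        intergenic_extra_min=2600,
        intergenic_extra_max=3600,
    )


def call_nucleosomes_genome(
    fragments: list[FragmentRecord],
    annotation: GenomeAnnotation,
    params: CallerParams | None = None,
    sigma_bp: float = 20.0,
) -> list[NucleosomeCall]:
    """Smooth midpoint density and call nucleosomes on every data contig."""
    calls: list[NucleosomeCall] = []
    for c in annotation.contigs:
        if c.is_control:
            continue
        track = smooth_track(
            occupancy_from_fragments(fragments, c.name, c.length, mode="midpoint"),
            sigma_bp=sigma_bp,
        )
        calls.extend(call_nucleosomes(track, params))
    return calls


def nucleosome_spacing_pipeline(
    config: SimulationConfig,
    genotype: str = "wt",
    category_filter: str = "mainpeak",
    bin_width: int = 5,
    classes: dict[str, str] | None = None,
) -> DistanceHistogram:
    """Fragments → smoothed midpoint density → calls → adjacent distances."""
    annotation = build_genome(config)
    fragments, _ = simulate_mnase_fragments(annotation, config, genotype, classes)
    calls = call_nucleosomes_genome(fragments, annotation)
    return adjacent_distances(calls, category_filter=category_filter, bin_width=bin_width)


def tss_metaplot_pipeline(
    config: SimulationConfig,
    genotype: str = "wt",
    classes: dict[str, str] | None = None,
    window_bp: int = 1000,
    bin_bp: int = 10,
) -> MetaplotMatrix:
    """Fragments → footprint coverage → class-stratified TSS metaplot.

    When ``classes`` is None the per-gene labels come from the wild-type
    RPKM of a simulated count table, thresholded at the study's < 1 / > 5
    bounds (the same classification the fold-change analysis uses).
    """
    annotation = build_genome(config)
    if classes is None:
        table, _ = simulate_counts(annotation, config)
        rpkm = compute_rpkm(table)
        labels = classify_by_wt_rpkm(
            rpkm, table.samples_of("wt"),
            low_max=config.low_rpkm_max, high_min=config.high_rpkm_min,
        )
        classes = labels.to_dict()
    fragments, _ = simulate_mnase_fragments(annotation, config, genotype, classes)
    tracks = {
        c.name: occupancy_from_fragments(fragments, c.name, c.length, mode="footprint_coverage")
        for c in annotation.contigs
        if not c.is_control
    }
    return tss_metaplot(tracks, annotation.genes, classes, window_bp=window_bp, bin_bp=bin_bp)


def conversion_rate_pipeline(config: SimulationConfig, genotype: str = "wt") -> tuple[float, int]:
    """Simulate the control contig and estimate the conversion rate.

    Returns the pooled estimate (%) and the number of read observations it
    is based on.
    """
    annotation = build_genome(config)
    records, _ = simulate_cytosine_report(annotation, config, genotype)
    control = annotation.control_contig
    estimate = estimate_conversion_rate(records, control)
    n_obs = sum(r.coverage for r in records if r.contig == control)
    return estimate, n_obs


def methylation_comparison_pipeline(
    config: SimulationConfig,
    min_fraction: float = 0.05,
    min_coverage: int = 1,
    welch: bool = False,
) -> GenotypeComparison:
    """Simulate both genotypes and compare per-feature methylation."""
    annotation = build_genome(config)
    index = assign_feature_classes(annotation, upstream_len=config.upstream_len)
    aggs = {}
    for genotype in ("wt", "mutant"):
        records, _ = simulate_cytosine_report(annotation, config, genotype)
        calls = call_methylated(records, min_fraction=min_fraction, min_coverage=min_coverage)
        aggs[genotype] = aggregate_by_feature(calls, index)
    return compare_genotypes(aggs["wt"], aggs["mutant"], welch=welch)
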