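import numpy as np
import pytest

import chromdev as cd


@pytest.fixture
def toy_annotation() -> cd.GenomeAnnotation:
    """A hand-built 10 kb two-contig genome with genes on both strands,
    a repeat overlapping a gene, and an unmethylated control contig."""
    return cd.GenomeAnnotation(
        contigs=[
            cd.ContigSpec("chr1", 10_000),
            cd.ContigSpec("chr2", 2_100),
            cd.ContigSpec("chrM", 5_000, is_control=True),
        ],
        genes=[
            cd.GeneRecord("gA", "chr1", 1_000, 2_000, "+"),
            cd.GeneRecord("gB", "chr1", 4_000, 6_000, "-"),
            cd.GeneRecord("gC", "chr1", 8_000, 9_500, "+"),
            cd.GeneRecord("gD", "chr2", 1_000, 2_000, "-"),  # upstream truncated
        ],
        repeats=[
            cd.IntervalRecord("chr1", 2_500, 3_000, "repA"),
            cd.IntervalRecord("chr1", 5_500, 5_800, "repB"),  # inside gB
        ],
    )


@pytest.fixture(scope="session")
def default_config() -> cd.SimulationConfig:
    return cd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_genome(default_config) -> cd.GenomeAnnotation:
    return cd.build_genome(default_config)


@pytest.fixture(scope="session")
def sim_counts(default_config, sim_genome):
    return cd.simulate_counts(sim_genome, default_config)


@pytest.fixture(scope="session")
def mnase_pipeline():
    """Full MNase simulation + calling on a non-colliding array layout,
    shared by the caller-recovery, spacing and acceptance checks."""
    cfg = cd.isolated_array_config(seed=1)
    ann = cd.build_genome(cfg)
    _, truth = cd.simulate_counts(ann, cfg)
    classes = cd.expression_classes_from_truth(truth)
    fragments, dyads = cd.simulate_mnase_fragments(ann, cfg, "wt", classes)
    calls = cd.call_nucleosomes_genome(fragments, ann)
    return {
        "config": cfg,
        "annotation": ann,
        "classes": classes,
        "fragments": fragments,
        "true_dyads": dyads,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def meth_config() -> cd.SimulationConfig:
    """Study-scale methylation comparison layout: >= 200 features per class."""
    return cd.SimulationConfig(seed=1, n_repeats=200, intergenic_extra_max=2600)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
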