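"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure the downstream analyses assume, with
ground truth attached, so every stage is testable without sequencing data:

* a genome annotation with non-overlapping genes, intergenic repeats and a
  fully unmethylated control contig;
* negative-binomially dispersed RNA-seq counts in which the mutant
  upregulates a random subset of weakly expressed genes;
* phased nucleosome arrays around TSSs with a nucleosome-depleted region
  (NDR) upstream whose width depends on the gene's expression class, the
  array flanking the NDR on both sides;
* per-cytosine bisulfite calls with class-specific methylation rates
  (repeats > genes), a global mutant reduction, and incomplete-conversion
  noise estimated from the control contig.

A single root seed deterministically derives per-generator substreams, so
adding one generator never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import assign_feature_classes
from .records import (
    ConfigError,
    ContigSpec,
    CountTable,
    CytosineRecord,
    FragmentRecord,
    GeneRecord,
    GenomeAnnotation,
    IntervalRecord,
    SimulationError,
)

# fixed substream keys; genotype-specific generators get their own streams
_STREAMS = {
    "genome": 0,
    "counts": 1,
    "mnase_wt": 2,
    "mnase_mutant": 3,
    "meth_wt": 4,
    "meth_mutant": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic, mutually independent RNG substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],)))


@dataclass
class SimulationConfig:
    """All knobs of the generator, with study-condition defaults.

    Nucleosome geometry follows the canonical chromatin picture: a 147 bp
    core particle and linkers in the 10–80 bp range; the default 33 bp
    linker gives a 180 bp repeat length, the peak spacing the analyses are
    designed to recover. Methylation rates are higher in repeats than in
    genes, and the mutant multiplier scales all true rates down.
    """

    seed: int = 0

    # genome layout
    n_contigs: int = 4
    contig_length: int = 250_000
    n_genes: int = 200
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 300.0
    gene_min_length: int = 300
    n_repeats: int = 40
    repeat_length: int = 400
    upstream_len: int = 500
    intergenic_extra_min: int = 600
    intergenic_extra_max: int = 2000

    # expression
    n_replicates: int = 2
    baseline_mean_min: float = 0.5
    baseline_mean_max: float = 50000.0
    nb_dispersion: float = 0.1
    mutant_low_effect: float = 1.0  # log2 shift on affected low-expressed genes
    p_effect: float = 0.5
    low_rpkm_max: float = 1.0
    high_rpkm_min: float = 5.0

    # nucleosomes
    footprint_bp: int = 147
    linker_bp: int = 33
    dyad_jitter_sd: float = 10.0
    length_jitter_sd: float = 10.0
    fragments_per_nucleosome: float = 30.0
    ndr_width_low: int = 120
    ndr_width_neither: int = 150
    ndr_width_high: int = 300
    upstream_array_bp: int = 1200
    background_fragments_per_kb: float = 2.0

    # methylation
    cytosine_density: float = 0.02
    rate_repeat: float = 0.08
    rate_gene_body: float = 0.015
    rate_upstream: float = 0.02
    rate_background: float = 0.005
    mutant_rate_multiplier: float = 0.6
    conversion_probability: float = 0.99
    coverage_mean: float = 20.0
    control_contig_length: int = 20_000
    control_n_cytosines: int = 10_000

    def __post_init__(self) -> None:
        if self.footprint_bp <= 0:
            raise ConfigError("footprint_bp must be positive")
        for name in (
            "p_effect",
            "rate_repeat",
            "rate_gene_body",
            "rate_upstream",
            "rate_background",
            "conversion_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.baseline_mean_min <= 0 or self.baseline_mean_max < self.baseline_mean_min:
            raise ConfigError("baseline mean range must satisfy 0 < min <= max")
        if self.control_n_cytosines > self.control_contig_length:
            raise ConfigError("control contig too short for requested cytosines")

    def ndr_width(self, expr_class: str) -> int:
        return {
            "low": self.ndr_width_low,
            "high": self.ndr_width_high,
            "neither": self.ndr_width_neither,
        }[expr_class]

    @property
    def repeat_len_bp(self) -> int:
        """Nucleosome repeat length: footprint + linker."""
        return self.footprint_bp + self.linker_bp


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Parse a flat ``key = value`` config file; unknown keys are errors."""
    fields = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            ftype = fields[key]
            kwargs[key] = float(value) if "float" in str(ftype) else int(value)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def build_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes (with upstream clearance) and intergenic
    repeats on equal-length contigs, plus the flagged control contig."""
    rng = substream(config.seed, "genome")
    contigs = [
        ContigSpec(f"contig_{i + 1:02d}", config.contig_length)
        for i in range(config.n_contigs)
    ]
    genes: list[GeneRecord] = []
    repeat_slots: list[tuple[str, int, int]] = []
    placed = 0
    margin = config.upstream_len + 200
    for c in contigs:
        cursor = margin
        while placed < config.n_genes:
            glen = int(
                max(
                    config.gene_min_length,
                    round(rng.normal(config.gene_length_mean, config.gene_length_sd)),
                )
            )
            extra = int(
                rng.integers(config.intergenic_extra_min, config.intergenic_extra_max + 1)
            )
            if cursor + glen + config.upstream_len + extra > c.length - margin:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            placed += 1
            genes.append(
                GeneRecord(f"gene_{placed:05d}", c.name, cursor, cursor + glen, strand)
            )
            # clear of both neighbours' upstream windows
            slot_start = cursor + glen + config.upstream_len
            slot_end = cursor + glen + extra
            if slot_end - slot_start >= config.repeat_length:
                repeat_slots.append((c.name, slot_start, slot_end))
            cursor += glen + config.upstream_len + extra
    if placed < config.n_genes:
        raise SimulationError(
            f"cannot place {config.n_genes} genes: capacity {placed} with "
            f"{config.n_contigs} x {config.contig_length} bp contigs"
        )

    # candidate repeat intervals: tile each slot with 50 bp spacing
    candidates: list[tuple[str, int]] = []
    for contig, s, e in repeat_slots:
        pos = s
        while pos + config.repeat_length <= e:
            candidates.append((contig, pos))
            pos += config.repeat_length + 50
    if len(candidates) < config.n_repeats:
        raise SimulationError(
            f"cannot place {config.n_repeats} repeats: only {len(candidates)} "
            f"intergenic candidate positions available"
        )
    chosen = rng.choice(len(candidates), size=config.n_repeats, replace=False)
    repeats = [
        IntervalRecord(
            candidates[i][0],
            candidates[i][1],
            candidates[i][1] + config.repeat_length,
            f"rep{k:05d}",
        )
        for k, i in enumerate(sorted(chosen))
    ]
    contigs.append(
        ContigSpec("contig_ctrl", config.control_contig_length, is_control=True)
    )
    return GenomeAnnotation(contigs=contigs, genes=genes, repeats=repeats)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[CountTable, pd.DataFrame]:
    """Simulate a wild-type/mutant count table with ground truth.

    Per-gene baseline means are log-uniform; a fraction ``p_effect`` of genes
    whose baseline RPKM falls below ``low_rpkm_max`` receive a
    ``mutant_low_effect`` log2 shift in the mutant. Counts are negative
    binomial with configured dispersion. Returns the table and a truth frame
    with columns gene_id, baseline_mean, baseline_rpkm, log2_effect,
    expr_class.
    """
    if config.n_replicates < 2:
        raise ConfigError("need >= 2 replicates per genotype")
    rng = substream(config.seed, "counts")
    genes = annotation.genes
    n = len(genes)
    lengths = np.array([g.length for g in genes], dtype=float)
    mu = np.exp(
        rng.uniform(
            np.log(config.baseline_mean_min), np.log(config.baseline_mean_max), size=n
        )
    )
    lib_expected = mu.sum() if n else 1.0
    baseline_rpkm = 1e9 * mu / (lengths * lib_expected) if n else np.array([])
    low = baseline_rpkm < config.low_rpkm_max
    affected = low & (rng.random(n) < config.p_effect)
    delta = np.where(affected, config.mutant_low_effect, 0.0)

    sample_ids, genotypes, reps, cols = [], [], [], []
    for genotype, mult in (("wt", np.ones(n)), ("mutant", 2.0 ** delta)):
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{genotype}_{r}")
            genotypes.append(genotype)
            reps.append(r)
            cols.append(_nb_draw(rng, mu * mult, config.nb_dispersion))
    gene_ids = [g.gene_id for g in genes]
    counts = pd.DataFrame(
        np.column_stack(cols) if n else np.empty((0, len(cols)), dtype=int),
        index=gene_ids,
        columns=sample_ids,
        dtype=int,
    )
    meta = pd.DataFrame(
        {"genotype": genotypes, "replicate": reps}, index=pd.Index(sample_ids, name="sample_id")
    )
    expr_class = np.where(
        baseline_rpkm < config.low_rpkm_max,
        "low",
        np.where(baseline_rpkm > config.high_rpkm_min, "high", "neither"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_mean": mu,
            "baseline_rpkm": baseline_rpkm,
            "log2_effect": delta,
            "expr_class": expr_class,
        }
    )
    table = CountTable(
        counts=counts,
        gene_lengths=pd.Series(lengths.astype(int), index=gene_ids),
        sample_meta=meta,
    )
    return table, truth


def expression_classes_from_truth(truth: pd.DataFrame) -> dict[str, str]:
    """Per-gene true expression class labels (low / high / neither)."""
    return dict(zip(truth["gene_id"], truth["expr_class"]))


# ---------------------------------------------------------------------------
# MNase fragments
# ---------------------------------------------------------------------------

def _true_dyads(gene: GeneRecord, config: SimulationConfig, ndr: int) -> list[int]:
    """Phased array dyads for one gene: +1, +2, ... downstream of the TSS and
    a mirrored array upstream of the NDR (the −1 nucleosome and beyond)."""
    rep = config.repeat_len_bp
    half = config.footprint_bp // 2
    sign = 1 if gene.strand == "+" else -1
    dyads = []
    # downstream array across the gene body
    d = gene.tss + sign * half
    while gene.start <= d < gene.end:
        dyads.append(d)
        d += sign * rep
    # upstream array beyond the NDR
    d = gene.tss - sign * (ndr + half)
    limit = config.upstream_array_bp
    covered = 0
    while covered < limit:
        dyads.append(d)
        d -= sign * rep
        covered += rep
    return dyads


def simulate_mnase_fragments(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    genotype: str = "wt",
    classes: dict[str, str] | None = None,
) -> tuple[list[FragmentRecord], pd.DataFrame]:
    """Simulate MNase fragments from phased nucleosome arrays.

    Each true dyad emits ``Poisson(fragments_per_nucleosome)`` fragments with
    Gaussian midpoint jitter and Gaussian length jitter around the footprint;
    uniform background fragments are added at ``background_fragments_per_kb``.
    Nucleosome geometry is genotype-independent (the mutant's chromatin is
    wild-type-like); the genotype only selects the random substream. Returns
    fragments plus a truth frame of per-gene dyad positions.
    """
    if genotype not in ("wt", "mutant"):
        raise ConfigError(f"unknown genotype {genotype!r}")
    if classes is None:
        _, truth = simulate_counts(annotation, config)
        classes = expression_classes_from_truth(truth)
    rng = substream(config.seed, f"mnase_{genotype}")
    lengths = annotation.contig_lengths
    fragments: list[FragmentRecord] = []
    truth_rows = []
    for gene in annotation.genes:
        ndr = config.ndr_width(classes.get(gene.gene_id, "neither"))
        clen = lengths[gene.contig]
        for k, dyad in enumerate(_true_dyads(gene, config, ndr)):
            if not 0 <= dyad < clen:
                continue
            truth_rows.append((gene.gene_id, k, gene.contig, dyad))
            n_frag = rng.poisson(config.fragments_per_nucleosome)
            if n_frag == 0:
                continue
            mids = np.rint(dyad + rng.normal(0.0, config.dyad_jitter_sd, n_frag)).astype(int)
            flens = np.rint(
                config.footprint_bp + rng.normal(0.0, config.length_jitter_sd, n_frag)
            ).astype(int)
            flens = np.maximum(flens, 50)
            starts = mids - flens // 2
            ends = starts + flens
            # fragments straddling a contig edge would not map; drop them
            for s, e in zip(starts, ends):
                if s >= 0 and e <= clen:
                    fragments.append(FragmentRecord(gene.contig, int(s), int(e)))
    # uniform background everywhere (including NDRs) on non-control contigs
    for c in annotation.contigs:
        if c.is_control:
            continue
        n_bg = rng.poisson(config.background_fragments_per_kb * c.length / 1000.0)
        starts = rng.integers(0, max(1, c.length - config.footprint_bp), size=n_bg)
        for s in starts:
            fragments.append(
                FragmentRecord(c.name, int(s), int(min(s + config.footprint_bp, c.length)))
            )
    fragments.sort(key=lambda f: (f.contig, f.start, f.end))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "nuc_index", "contig", "dyad"])
    return fragments, truth


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

_CLASS_PRECEDENCE = ("repeat", "gene_body", "upstream")


def simulate_cytosine_report(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    genotype: str = "wt",
) -> tuple[list[CytosineRecord], pd.DataFrame]:
    """Simulate a per-cytosine report with feature-class methylation rates.

    True rates: repeats > gene bodies ~ upstream > background, all scaled by
    ``mutant_rate_multiplier`` in the mutant; the control contig is fully
    unmethylated. Observed methylated counts are
    ``Binomial(coverage, r + (1 - r)(1 - conversion_probability))`` — failed
    conversions read as spurious methylation. Returns records (1-based
    positions) plus a truth frame with per-site true rates.
    """
    if genotype not in ("wt", "mutant"):
        raise ConfigError(f"unknown genotype {genotype!r}")
    rng = substream(config.seed, f"meth_{genotype}")
    index = assign_feature_classes(annotation, upstream_len=config.upstream_len)
    mult = config.mutant_rate_multiplier if genotype == "mutant" else 1.0
    base_rates = {
        "repeat": config.rate_repeat,
        "gene_body": config.rate_gene_body,
        "upstream": config.rate_upstream,
    }
    records: list[CytosineRecord] = []
    truth_rows = []
    contexts = np.array(["CG", "CHG", "CHH"])
    fail = 1.0 - config.conversion_probability
    for c in annotation.contigs:
        if c.is_control:
            positions = np.sort(
                rng.choice(c.length, size=config.control_n_cytosines, replace=False)
            )
            rates = np.zeros(len(positions))
        else:
            mask = rng.random(c.length) < config.cytosine_density
            positions = np.flatnonzero(mask)
            rates = np.empty(len(positions))
            for i, p in enumerate(positions):
                classes = {m[0] for m in index.memberships(c.name, int(p))}
                for cls in _CLASS_PRECEDENCE:
                    if cls in classes:
                        rates[i] = base_rates[cls] * mult
                        break
                else:
                    rates[i] = config.rate_background * mult
        strands = np.where(rng.random(len(positions)) < 0.5, "+", "-")
        ctx = contexts[rng.integers(0, 3, size=len(positions))]
        coverage = rng.poisson(config.coverage_mean, size=len(positions))
        observed = rates + (1.0 - rates) * fail
        meth = rng.binomial(coverage, observed)
        for p, s, cx, cov, m, r in zip(positions, strands, ctx, coverage, meth, rates):
            records.append(
                CytosineRecord(c.name, int(p) + 1, str(s), int(m), int(cov - m), str(cx))
            )
            truth_rows.append((c.name, int(p) + 1, float(r)))
    truth = pd.DataFrame(truth_rows, columns=["contig", "pos", "true_rate"])
    truth["conversion_probability"] = config.conversion_probability
    return records, truth
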