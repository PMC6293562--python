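"""Core domain types shared across the pipeline.

All internal coordinates are 0-based half-open; conversion to/from 1-based
conventions (GFF3, cytosine reports) happens only at format boundaries in
:mod:`chromdev.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ChromdevError(Exception):
    """Base class for all package errors."""


class ParseError(ChromdevError):
    """A file could not be parsed."""


class ValidationError(ChromdevError):
    """Parsed data violates an invariant."""


class ConfigError(ChromdevError):
    """A simulation config is invalid or contains unknown keys."""


class SimulationError(ChromdevError):
    """Requested simulation cannot be realised (e.g. capacity exceeded)."""


@dataclass(frozen=True)
class ContigSpec:
    """A contig with its length; ``is_control`` marks the fully unmethylated
    control contig used for bisulfite conversion-rate estimation."""

    name: str
    length: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"contig {self.name!r}: length must be > 0")


@dataclass(frozen=True)
class GeneRecord:
    """A gene span with strand-aware TSS (0-based half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on −."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntervalRecord:
    """A labelled genomic interval (e.g. an annotated repeat)."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.label!r}: start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class FragmentRecord:
    """A mapped MNase fragment (BED convention, unstranded)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"fragment start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CytosineRecord:
    """Per-cytosine bisulfite calls. ``pos`` is 1-based as in the
    cytosine-report format; it is converted at aggregation time."""

    contig: str
    pos: int
    strand: str
    meth_count: int
    unmeth_count: int
    context: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"cytosine pos {self.pos} must be >= 1")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValidationError("cytosine counts must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.context not in ("CG", "CHG", "CHH"):
            raise ValidationError(f"bad context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclass
class GenomeAnnotation:
    """Coordinate backbone for all aggregation: contigs, genes, repeats."""

    contigs: list[ContigSpec]
    genes: list[GeneRecord] = field(default_factory=list)
    repeats: list[IntervalRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValidationError("contig names are not unique")
        lengths = self.contig_lengths
        for g in self.genes:
            if g.contig not in lengths:
                raise ValidationError(f"gene {g.gene_id}: unknown contig {g.contig}")
            if g.end > lengths[g.contig]:
                raise ValidationError(
                    f"gene {g.gene_id} extends past contig {g.contig} "
                    f"({g.end} > {lengths[g.contig]})"
                )
        for r in self.repeats:
            if r.contig not in lengths or r.end > lengths[r.contig]:
                raise ValidationError(f"repeat {r.label!r} outside contig bounds")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.contigs}

    @property
    def control_contig(self) -> str | None:
        for c in self.contigs:
            if c.is_control:
                return c.name
        return None


@dataclass
class CountTable:
    """Gene × sample read counts with per-gene lengths and sample metadata.

    ``counts`` is an integer DataFrame (index = gene ids, columns = sample
    ids); ``gene_lengths`` a Series over the same genes; ``sample_meta`` a
    DataFrame indexed by sample id with columns ``genotype``, ``replicate``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValidationError("duplicate gene ids in count table")
        if not self.counts.columns.is_unique:
            raise ValidationError("duplicate sample ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if not list(self.gene_lengths.index) == list(self.counts.index):
            raise ValidationError("gene_lengths index does not match counts")
        if (self.gene_lengths.to_numpy() <= 0).any():
            raise ValidationError("gene lengths must be positive")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples missing metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, genotype: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["genotype"] == genotype])


@dataclass
class OccupancyTrack:
    """Per-base non-negative occupancy vector for one contig.

    ``mode`` records provenance: ``footprint_coverage`` (fragment pileup),
    ``midpoint`` (raw fragment-midpoint counts) or
    ``smoothed_midpoint_density`` (after Gaussian smoothing).
    """

    contig: str
    values: np.ndarray
    mode: str = "footprint_coverage"
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("occupancy track must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValidationError("occupancy track contains non-finite values")
        if (self.values < 0).any():
            raise ValidationError("occupancy track contains negative values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with Tukey whiskers (1.5 × IQR rule).

    Quartiles use linear interpolation between order statistics; whiskers are
    the most extreme data points within the 1.5 × IQR fences.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_summary(values) -> BoxplotSummary:
    """Summarise a 1-D collection of finite values for a boxplot."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot summarise an empty set of values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
    )
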