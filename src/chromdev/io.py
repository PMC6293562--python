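"""Readers and writers for the standard formats the pipeline touches, plus
position-to-feature assignment.

Conventions
-----------
GFF3 and cytosine reports are 1-based on disk and converted to the internal
0-based half-open convention on read (and back on write). BED and bedGraph
are already 0-based half-open and pass through verbatim. A
``##control-contig <name>`` GFF3 pragma flags the unmethylated control
contig used for conversion-rate estimation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .records import (
    ContigSpec,
    CountTable,
    CytosineRecord,
    FragmentRecord,
    GeneRecord,
    GenomeAnnotation,
    IntervalRecord,
    OccupancyTrack,
    ParseError,
    ValidationError,
)

CONTROL_PRAGMA = "control-contig"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> GenomeAnnotation:
    """Read gene features and contig specs from a GFF3 file.

    Contig lengths come from ``##sequence-region`` pragmas; the optional
    ``##control-contig`` pragma marks the control contig. GFF 1-based
    inclusive coordinates become 0-based half-open.
    """
    contigs: list[ContigSpec] = []
    control: str | None = None
    # directives first (also works for gene-less files)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: malformed sequence-region")
                contigs.append((parts[1], int(parts[2]), int(parts[3])))
            elif line.startswith(f"##{CONTROL_PRAGMA}"):
                control = line.split()[1]
            elif line and not line.startswith("#"):
                if len(line.split("\t")) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
    if not contigs:
        raise ParseError(f"{path}: no ##sequence-region pragmas found")
    specs = [
        ContigSpec(name, end - start + 1, is_control=(name == control))
        for name, start, end in contigs
    ]

    genes: list[GeneRecord] = []
    has_features = any(
        not ln.startswith("#") and ln.strip() for ln in open(path)
    )
    if has_features:
        try:
            db = gffutils.create_db(
                str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
            )
        except Exception as exc:  # noqa: BLE001 - surface as our parse error
            raise ParseError(f"{path}: GFF3 parse failed: {exc}") from exc
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            genes.append(
                GeneRecord(
                    gene_id=feat.id,
                    contig=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    return GenomeAnnotation(contigs=specs, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write an annotation as GFF3 (genes only), 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in annotation.contigs:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        if annotation.control_contig is not None:
            fh.write(f"##{CONTROL_PRAGMA} {annotation.control_contig}\n")
        for g in annotation.genes:
            fh.write(
                f"{g.contig}\tchromdev\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _read_bed_frame(path: str | os.PathLike) -> pd.DataFrame | None:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return None
    return df


def _check_bed_coords(df: pd.DataFrame, path) -> tuple[np.ndarray, np.ndarray]:
    try:
        start = df[1].astype(int).to_numpy()
        end = df[2].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer BED coordinates: {exc}") from exc
    if (start >= end).any():
        bad = int(np.argmax(start >= end))
        raise ValidationError(f"{path}: line {bad + 1}: start >= end")
    return start, end


def read_bed_fragments(path: str | os.PathLike) -> list[FragmentRecord]:
    """Read BED3 intervals as MNase fragments (0-based half-open)."""
    df = _read_bed_frame(path)
    if df is None:
        return []
    start, end = _check_bed_coords(df, path)
    contig = df[0].to_numpy()
    return [FragmentRecord(c, int(s), int(e)) for c, s, e in zip(contig, start, end)]


def read_bed_intervals(path: str | os.PathLike) -> list[IntervalRecord]:
    """Read BED intervals with an optional 4th name column as labels."""
    df = _read_bed_frame(path)
    if df is None:
        return []
    start, end = _check_bed_coords(df, path)
    labels = df[3].to_numpy() if df.shape[1] > 3 else [""] * len(df)
    return [
        IntervalRecord(c, int(s), int(e), str(l))
        for c, s, e, l in zip(df[0].to_numpy(), start, end, labels)
    ]


def write_bed(records, path: str | os.PathLike) -> None:
    """Write fragments or labelled intervals as BED3/BED4."""
    with open(path, "w") as fh:
        for r in records:
            label = getattr(r, "label", None)
            if label:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{label}\n")
            else:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Cytosine report (Bismark cytosine-report dialect)
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | os.PathLike) -> list[CytosineRecord]:
    """Read a per-cytosine TSV: contig, pos (1-based), strand, meth, unmeth,
    context. Records are returned in file order with no aggregation."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "pos", "strand", "meth", "unmeth", "context"],
            dtype={"contig": str, "strand": str, "context": str},
        )
    except pd.errors.EmptyDataError:
        return []
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValidationError(f"{path}: negative methylation counts")
    return [
        CytosineRecord(r.contig, int(r.pos), r.strand, int(r.meth), int(r.unmeth), r.context)
        for r in df.itertuples(index=False)
    ]


def write_cytosine_report(records, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig}\t{r.pos}\t{r.strand}\t{r.meth_count}\t"
                f"{r.unmeth_count}\t{r.context}\n"
            )


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------

def read_count_table(
    counts_path: str | os.PathLike, samples_path: str | os.PathLike
) -> CountTable:
    """Read a gene × sample count TSV plus its sample sheet.

    The count table has columns ``gene_id``, ``length``, then one column per
    sample; the sample sheet has ``sample_id``, ``genotype``, ``replicate``.
    Counts must be integers.
    """
    df = pd.read_csv(counts_path, sep="\t")
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise ParseError(f"{counts_path}: need 'gene_id' and 'length' columns")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{counts_path}: duplicate gene ids")
    df = df.set_index("gene_id")
    lengths = df.pop("length").astype(int)
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            raise ParseError(
                f"{counts_path}: column {col!r} contains non-integer counts"
            )
    meta = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    if not {"genotype", "replicate"} <= set(meta.columns):
        raise ParseError(f"{samples_path}: need 'genotype' and 'replicate' columns")
    return CountTable(counts=df, gene_lengths=lengths, sample_meta=meta)


def write_count_table(
    table: CountTable,
    counts_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(samples_path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: OccupancyTrack, path: str | os.PathLike) -> None:
    """Write a track as run-length-compressed bedGraph (zero runs included,
    so output is deterministic and diffs cleanly)."""
    v = track.values
    if not np.isfinite(v).all():
        raise ValidationError("bedGraph requires finite values")
    with open(path, "w") as fh:
        if len(v) == 0:
            return
        boundaries = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(v)]))
        for s, e in zip(starts, ends):
            fh.write(f"{track.contig}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path: str | os.PathLike, contig_length: int) -> OccupancyTrack:
    """Parse a single-contig bedGraph back into a per-base track."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "start", "end", "value"])
    values = np.zeros(contig_length)
    for r in df.itertuples(index=False):
        values[r.start:r.end] = r.value
    return OccupancyTrack(contig=str(df["contig"].iloc[0]), values=values, mode="parsed")


# ---------------------------------------------------------------------------
# Feature assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One aggregation unit: a gene body, an upstream window, or a repeat."""

    feature_id: str
    feature_class: str  # gene_body | upstream | repeat
    contig: str
    start: int
    end: int


@dataclass
class FeatureIndex:
    """Per-contig interval index mapping positions to feature memberships.

    Memberships may overlap: a position inside both a gene and a repeat
    belongs to both features. ``contig_lengths`` is kept so callers can
    validate coordinates against the same backbone the index was built from.
    """

    features: list[Feature]
    contig_lengths: dict[str, int]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._trees:
            for f in self.features:
                self._trees.setdefault(f.contig, IntervalTree()).addi(
                    f.start, f.end, (f.feature_class, f.feature_id)
                )

    def memberships(self, contig: str, pos: int) -> set[tuple[str, str]]:
        """All (feature_class, feature_id) pairs covering a 0-based position."""
        tree = self._trees.get(contig)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}


def assign_feature_classes(
    annotation: GenomeAnnotation,
    upstream_len: int = 500,
    strand_aware: bool = True,
) -> FeatureIndex:
    """Build the gene-body / upstream / repeat feature index.

    Each gene yields a ``gene_body`` feature over its full primary-transcript
    span and an ``upstream`` feature of ``upstream_len`` bases on the TSS
    side (strand-aware by default), truncated at contig edges. Each repeat
    interval yields one ``repeat`` feature. Overlaps are all retained.
    """
    if upstream_len <= 0:
        raise ValidationError("upstream_len must be positive")
    lengths = annotation.contig_lengths
    features: list[Feature] = []
    for g in annotation.genes:
        features.append(Feature(g.gene_id, "gene_body", g.contig, g.start, g.end))
        if strand_aware and g.strand == "-":
            u_start, u_end = g.end, min(lengths[g.contig], g.end + upstream_len)
        else:
            u_start, u_end = max(0, g.start - upstream_len), g.start
        if u_start < u_end:
            features.append(Feature(g.gene_id, "upstream", g.contig, u_start, u_end))
    for i, r in enumerate(annotation.repeats):
        rid = r.label or f"rep{i:05d}"
        features.append(Feature(rid, "repeat", r.contig, r.start, r.end))
    return FeatureIndex(features=features, contig_lengths=lengths)
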