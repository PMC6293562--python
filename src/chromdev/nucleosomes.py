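"""Nucleosome positioning from MNase fragments: occupancy tracks, a
simplified peak caller with category labels, adjacent-dyad distance
histograms, and expression-stratified TSS metaplots.

The caller is a documented simplification of shape-based nucleosome
callers: Gaussian-smoothed fragment-midpoint density, local maxima above a
height floor, a merge rule producing ``MainPeak:doublet`` calls and a
relative-height band producing ``MainPeak+Shoulder`` / ``Shoulder`` labels.
Downstream analyses consume only dyad positions and categories, so this is
sufficient for spacing and metaplot work.

Occupancy for metaplots uses footprint coverage (what "occupancy" means);
calling uses smoothed midpoint density (midpoints localise dyads).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .records import FragmentRecord, GeneRecord, OccupancyTrack, ValidationError

MAIN_PEAK = "MainPeak"
DOUBLET = "MainPeak:doublet"
MAIN_WITH_SHOULDER = "MainPeak+Shoulder"
SHOULDER = "Shoulder"
CATEGORIES = (MAIN_PEAK, DOUBLET, MAIN_WITH_SHOULDER, SHOULDER)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def occupancy_from_fragments(
    fragments: list[FragmentRecord],
    contig: str,
    contig_length: int,
    mode: str = "footprint_coverage",
) -> OccupancyTrack:
    """Per-base occupancy from fragments on one contig.

    ``footprint_coverage``: value at base b = number of fragments with
    start <= b < end. ``midpoint``: counts of fragment midpoints
    floor((start + end) / 2). Fragments extending past the contig are
    clipped and counted in ``n_clipped``.
    """
    if mode not in ("footprint_coverage", "midpoint"):
        raise ValidationError(f"unknown occupancy mode {mode!r}")
    values = np.zeros(contig_length)
    n_clipped = 0
    if mode == "footprint_coverage":
        diff = np.zeros(contig_length + 1)
        for f in fragments:
            if f.contig != contig:
                continue
            s, e = f.start, f.end
            if s < 0 or e > contig_length:
                n_clipped += 1
                s, e = max(0, s), min(contig_length, e)
            if e > s:
                diff[s] += 1
                diff[e] -= 1
        values = np.cumsum(diff[:-1])
    else:
        for f in fragments:
            if f.contig != contig:
                continue
            m = f.midpoint
            if 0 <= m < contig_length:
                values[m] += 1
            else:
                n_clipped += 1
    return OccupancyTrack(contig=contig, values=values, mode=mode, n_clipped=n_clipped)


def smooth_track(track: OccupancyTrack, sigma_bp: float = 20.0) -> OccupancyTrack:
    """Gaussian smoothing (kernel truncated at ±4σ, reflective boundaries).

    Total mass is conserved; midpoint tracks become
    ``smoothed_midpoint_density``.
    """
    if sigma_bp <= 0:
        raise ValidationError("sigma_bp must be positive")
    smoothed = gaussian_filter1d(track.values, sigma=sigma_bp, mode="reflect", truncate=4.0)
    mode = "smoothed_midpoint_density" if track.mode == "midpoint" else track.mode
    return OccupancyTrack(
        contig=track.contig, values=np.maximum(smoothed, 0.0), mode=mode,
        n_clipped=track.n_clipped,
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the simplified caller.

    ``min_height_frac`` scales the track mean over its nonzero region into
    the candidate-peak floor; peaks closer than ``merge_dist`` merge into a
    doublet at their height-weighted centre; a neighbour at
    [``shoulder_min``, ``shoulder_max``] bp with relative height in
    [``shoulder_rel_lo``, ``shoulder_rel_hi``) is labelled a shoulder.
    """

    min_height_frac: float = 0.25
    merge_dist: int = 110
    shoulder_min: int = 75
    shoulder_max: int = 150
    shoulder_rel_lo: float = 0.4
    shoulder_rel_hi: float = 0.8
    footprint_bp: int = 147


@dataclass(frozen=True)
class NucleosomeCall:
    contig: str
    dyad: int
    start: int
    end: int
    category: str
    height: float


def candidate_peaks(values: np.ndarray, params: CallerParams) -> tuple[np.ndarray, float]:
    """Local maxima above the height floor (floor = min_height_frac × mean
    of the track over its nonzero region)."""
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return np.array([], dtype=int), 0.0
    floor = params.min_height_frac * float(nonzero.mean())
    peaks, _ = find_peaks(values, height=floor)
    return peaks, floor


def call_nucleosomes(
    track: OccupancyTrack, params: CallerParams | None = None
) -> list[NucleosomeCall]:
    """Call nucleosome dyads with category labels on a smoothed track."""
    params = params or CallerParams()
    v = track.values
    peaks, _ = candidate_peaks(v, params)
    if peaks.size == 0:
        return []
    heights = v[peaks]

    # merge clusters of peaks closer than merge_dist into doublets
    groups: list[list[int]] = [[0]]
    for i in range(1, len(peaks)):
        if peaks[i] - peaks[groups[-1][-1]] < params.merge_dist:
            groups[-1].append(i)
        else:
            groups.append([i])
    dyads, cat, hts = [], [], []
    for grp in groups:
        pos = peaks[grp].astype(float)
        h = heights[grp]
        if len(grp) == 1:
            dyads.append(int(pos[0]))
            cat.append(MAIN_PEAK)
            hts.append(float(h[0]))
        else:
            centre = int(round(np.average(pos, weights=h)))
            dyads.append(centre)
            cat.append(DOUBLET)
            hts.append(float(h.max()))

    # shoulder labelling between adjacent surviving MainPeak calls
    for i in range(len(dyads) - 1):
        if cat[i] != MAIN_PEAK or cat[i + 1] != MAIN_PEAK:
            continue
        d = dyads[i + 1] - dyads[i]
        if not params.shoulder_min <= d <= params.shoulder_max:
            continue
        lo, hi = (i, i + 1) if hts[i] < hts[i + 1] else (i + 1, i)
        ratio = hts[lo] / hts[hi] if hts[hi] > 0 else 1.0
        if params.shoulder_rel_lo <= ratio < params.shoulder_rel_hi:
            cat[hi] = MAIN_WITH_SHOULDER
            cat[lo] = SHOULDER

    half = params.footprint_bp // 2
    n = len(v)
    return [
        NucleosomeCall(
            contig=track.contig,
            dyad=d,
            start=max(0, d - half),
            end=min(n, d + half + 1),
            category=c,
            height=h,
        )
        for d, c, h in zip(dyads, cat, hts)
    ]


# ---------------------------------------------------------------------------
# adjacent-distance histogram
# ---------------------------------------------------------------------------

@dataclass
class DistanceHistogram:
    """Histogram of adjacent-dyad distances.

    Bins are left-closed and centred on integer multiples of ``bin_width``
    (a distance d falls in the bin with centre bin_width × round(d /
    bin_width)), so round repeat lengths sit on bin centres. ``mode`` is the
    centre of the maximal bin, ties broken toward the smaller distance;
    None when the histogram is empty.
    """

    bin_width: int
    centers: np.ndarray
    counts: np.ndarray
    distances: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def mode(self) -> float | None:
        if self.counts.size == 0 or self.counts.sum() == 0:
            return None
        return float(self.centers[int(np.argmax(self.counts))])


def adjacent_distances(
    calls: list[NucleosomeCall],
    category_filter: str = "all",
    bin_width: int = 5,
) -> DistanceHistogram:
    """Distances between consecutive retained calls on the same contig.

    ``category_filter='mainpeak'`` drops non-MainPeak calls first, then
    takes consecutive pairs of what remains; ``'all'`` keeps every call.
    """
    if category_filter not in ("all", "mainpeak"):
        raise ValidationError(f"unknown category filter {category_filter!r}")
    by_contig: dict[str, list[int]] = defaultdict(list)
    for c in calls:
        if category_filter == "mainpeak" and c.category != MAIN_PEAK:
            continue
        by_contig[c.contig].append(c.dyad)
    dists: list[int] = []
    for dyads in by_contig.values():
        dyads = sorted(dyads)
        dists.extend(b - a for a, b in zip(dyads, dyads[1:]) if b - a > 0)
    d = np.array(dists, dtype=int)
    if d.size == 0:
        return DistanceHistogram(bin_width, np.array([]), np.array([], dtype=int))
    k = np.floor(d / bin_width + 0.5).astype(int)
    counts = np.bincount(k)
    centers = np.arange(len(counts)) * bin_width
    return DistanceHistogram(bin_width, centers, counts, distances=d)


# ---------------------------------------------------------------------------
# TSS metaplots
# ---------------------------------------------------------------------------

@dataclass
class MetaplotMatrix:
    """Class-averaged, per-gene max-normalised occupancy around TSSs.

    ``positions`` are bin centres relative to the TSS (negative = upstream
    in the direction of transcription); values lie in [0, 1] because each
    gene's window is divided by its own maximum before averaging.
    """

    positions: np.ndarray
    class_means: dict[str, np.ndarray]
    n_genes: dict[str, int]
    n_excluded: int


def tss_metaplot(
    tracks: dict[str, OccupancyTrack],
    genes: list[GeneRecord],
    classes: dict[str, str],
    window_bp: int = 1000,
    bin_bp: int = 10,
) -> MetaplotMatrix:
    """Average normalised occupancy per expression class around TSSs.

    Per gene: extract occupancy over [tss − window, tss + window), orient so
    downstream is to the right (minus-strand windows are reversed), bin by
    mean, divide by the gene's window maximum, then average within each
    class. Genes whose window leaves the contig or is all-zero are excluded
    (counted in ``n_excluded``).
    """
    if window_bp % bin_bp:
        raise ValidationError("window_bp must be a multiple of bin_bp")
    n_bins = 2 * window_bp // bin_bp
    sums: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(n_bins))
    counts: dict[str, int] = defaultdict(int)
    n_excluded = 0
    for gene in genes:
        label = classes.get(gene.gene_id)
        if label is None:
            continue
        track = tracks.get(gene.contig)
        if track is None:
            n_excluded += 1
            continue
        L = len(track.values)
        if gene.strand == "+":
            lo, hi = gene.tss - window_bp, gene.tss + window_bp
            if lo < 0 or hi > L:
                n_excluded += 1
                continue
            window = track.values[lo:hi]
        else:
            lo, hi = gene.tss - window_bp + 1, gene.tss + window_bp + 1
            if lo < 0 or hi > L:
                n_excluded += 1
                continue
            window = track.values[lo:hi][::-1]
        peak = window.max()
        if peak <= 0:
            n_excluded += 1
            continue
        binned = window.reshape(n_bins, bin_bp).mean(axis=1)
        sums[label] += binned / binned.max()
        counts[label] += 1
    positions = -window_bp + bin_bp * (np.arange(n_bins) + 0.5)
    means = {k: sums[k] / counts[k] for k in sums if counts[k] > 0}
    return MetaplotMatrix(
        positions=positions,
        class_means=means,
        n_genes=dict(counts),
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class NdrMetrics:
    """Location and width of the nucleosome-depleted region upstream of the
    TSS in a class-averaged metaplot."""

    min_pos: float  # bp relative to TSS (negative = upstream)
    width: float  # bp below threshold around the minimum


def ndr_metrics(
    metaplot: MetaplotMatrix, expr_class: str, threshold_frac: float = 0.5
) -> NdrMetrics:
    """NDR minimum position and width at a fractional threshold.

    The minimum is the argmin of the class average over upstream positions;
    the width is the contiguous span around it where the profile stays below
    ``threshold_frac`` × the upstream-flank maximum. A flat profile has
    width 0.
    """
    if expr_class not in metaplot.class_means:
        raise ValidationError(f"no metaplot for class {expr_class!r}")
    profile = metaplot.class_means[expr_class]
    upstream = metaplot.positions < 0
    if not upstream.any():
        raise ValidationError("metaplot has no upstream coverage")
    up_vals = profile[upstream]
    i_min_up = int(np.argmin(up_vals))
    i_min = int(np.flatnonzero(upstream)[i_min_up])
    threshold = threshold_frac * float(up_vals.max())
    below = profile < threshold
    if not below[i_min]:
        return NdrMetrics(min_pos=float(metaplot.positions[i_min]), width=0.0)
    lo = i_min
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = i_min
    while hi + 1 < len(profile) and below[hi + 1]:
        hi += 1
    bin_bp = float(metaplot.positions[1] - metaplot.positions[0])
    return NdrMetrics(
        min_pos=float(metaplot.positions[i_min]),
        width=float((hi - lo + 1) * bin_bp),
    )
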