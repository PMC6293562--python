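# Methods

This note documents the models, conventions and design choices behind
`chromdev`, in the spirit of a methods supplement: what each analysis
computes, what the synthetic-data generator does and does not emulate, and
where the genuinely open choices were made.

## Coordinates and formats

All internal coordinates are 0-based half-open. Conversion happens only at
format boundaries: GFF3 and the per-cytosine report are 1-based on disk;
BED and bedGraph pass through verbatim. This keeps interval lengths
invariant under read/write round trips and confines off-by-one risk to two
well-tested functions. The TSS is `start` on the + strand and `end − 1` on
the − strand. The unmethylated control contig (the mitochondrial stand-in
used for conversion-rate QC) is flagged with an application-specific
`##control-contig <name>` GFF3 pragma, written and read by this package.

Feature assignment builds three feature classes per annotation: the gene
body (the full primary-transcript span — no exon-level resolution), a
500 bp upstream window on the TSS side (strand-aware by default, with a
flag to force left-of-start; truncated at contig edges rather than
dropped), and annotated repeats. Overlapping memberships are all retained;
there is no precedence hierarchy, because each feature instance is one
independent data point in the downstream box-plot statistics.

## Expression

RPKM uses counted reads (column sums) as the library size, so it is
exactly invariant to rescaling a sample's counts. Size factors are plain
median-of-ratios over genes with nonzero counts in every sample. Fold
changes are ratios of size-factor-normalised group means with a
pseudocount (default 0.5, configurable) on both numerator and denominator;
the MA x-coordinate is the mean of all normalised counts. One subtlety:
rescaling one sample rescales *all* samples' normalised counts by a common
factor under median-of-ratios, which cancels in the ratio but interacts
with a fixed pseudocount — the absorption invariance is exact on the ratio
itself and only approximate once the pseudocount matters (i.e. at very low
counts).

Expression classes come from the mean wild-type RPKM with strict
inequalities: `< 1` → low, `> 5` → high, otherwise neither. Distribution
summaries use linear-interpolation quartiles and Tukey 1.5 × IQR whiskers.
Differential-expression significance testing (dispersion modelling, Wald
tests, multiple-testing adjustment) is deliberately out of scope: the
stratified fold-change analysis is distributional, computed over all genes
(a caller-supplied gene list can restrict it).

Sample clustering computes Spearman correlations (average ranks for ties)
of log2 RPKM over genes with a nonzero measurement in all samples, then
average-linkage hierarchical clustering on `1 − ρ`. Samples are processed
in lexicographic id order so the leaf order is deterministic under ties.
These conventions (quartile rule, linkage, tie-breaks) are this package's
documented choices, not claims about any particular R configuration.

## Nucleosome positioning

Occupancy has two modes with distinct jobs: *footprint coverage* (fragment
pileup — what "occupancy" means in a metaplot) and *midpoint density*
(fragment midpoints localise dyads, smoothed for calling). Smoothing is a
discrete Gaussian (default σ = 20 bp, truncated at ±4σ) with reflective
boundaries, which conserves total mass.

The caller is a documented simplification of shape-based nucleosome
callers; downstream analyses consume only dyad positions and category
labels, so no wavelet/shape machinery is reproduced. Candidate peaks are
local maxima above a floor of 0.25 × the track mean over its nonzero
region. Peaks closer than 110 bp merge into one `MainPeak:doublet` at
their height-weighted centre (two nucleosomes cannot sit closer than a
footprint, so such pairs are one ambiguous particle). A neighbouring
maximum 75–150 bp away whose relative height lies in [0.4, 0.8) marks a
`MainPeak+Shoulder` / `Shoulder` pair; everything else is `MainPeak`. All
thresholds are configurable (`CallerParams`).

Adjacent-dyad distances are taken between consecutive retained calls on
the same contig — either all calls or MainPeak-only (drop first, then
pair). Histogram bins are left-closed, 5 bp wide, and **centred on integer
multiples of the bin width** (a distance `d` falls in the bin with centre
`w · round(d/w)`), so a 180 bp repeat length is reported as 180, not as an
edge-aligned 182.5. The mode is the centre of the maximal bin; ties break
toward the smaller distance.

TSS metaplots extract occupancy over ±1000 bp around each TSS (10 bp
bins by default; the exact window is a package choice), reverse
minus-strand windows so downstream is always to the right, divide each
gene's window by its own maximum (so every curve lies in [0, 1] and a
single gene's peak is exactly 1), and average within expression classes.
Genes whose window leaves the contig or is all-zero are excluded and
counted — whether to include zero-coverage genes is not a measurable
choice, so exclusion is documented rather than silent. NDR metrics are
computed on the class average: the minimum over upstream positions, and
the width of the contiguous span around it below 0.5 × the upstream-flank
maximum (a flat profile has width 0).

## Methylation

The conversion rate is the pooled (micro-averaged)
`100 · Σ unmeth / Σ coverage` over the control contig — matching how a
fully unmethylated control is read, and insensitive to per-site coverage
variation. The methylated-cytosine rule is inclusive: fraction ≥ 0.05 with
coverage ≥ `min_coverage` (default 1, i.e. no extra filter; raising it
guards the 5% rule against low-coverage noise). All sequence contexts
(CG/CHG/CHH) are aggregated by default with an optional filter upstream of
this package's scope.

Per-feature percentages use **covered cytosines** as the denominator — the
only denominator estimable from count data without the genome sequence;
both strands count independently, and features with no covered cytosine
are excluded with a reported count. Genotype comparison runs a two-sided
two-sample t-test per feature class (pooled-variance Student's by default,
Welch optional — both provided since the choice is conventional).
Zero-variance inputs return a flagged degenerate result (t = 0, p = 1 for
equal means; p = 0 with a warning otherwise) instead of raising.

## Synthetic data

The generator is the package's study stand-in; its defaults are the
conditions the analyses assume.

* **Genome**: equal-length contigs (4 × 250 kb by default) with
  non-overlapping genes (length ~ N(1500, 300²) bp, ≥ 300), each followed
  by a 500 bp upstream clearance plus a random intergenic gap; repeats
  (400 bp) are placed only in intergenic space clear of any upstream
  window. A flagged 20 kb control contig carries no features. Requested
  features that cannot fit raise a capacity error.
* **Counts**: per-gene baseline means are log-uniform over [0.5, 5 × 10⁴]
  expected counts, giving ~10⁶-read libraries at 200 genes (and ~10⁷ at
  2000), so the RPKM < 1 / > 5 class thresholds select genuinely weak and
  strong genes as they would in a real library. Counts are negative
  binomial with `var = μ + α μ²` (α = 0.1; α → 0 recovers Poisson). In the
  mutant, each low-baseline gene receives a +1 log2 shift with probability
  0.5; ground truth records every per-gene effect.
* **Nucleosomes**: canonical geometry — 147 bp footprint, fixed 33 bp
  linker (180 bp repeat length, within the usual 10–80 bp linker range).
  The +1 dyad sits half a footprint downstream of the TSS with successive
  dyads every repeat length across the gene body. The NDR is a hard
  exclusion zone upstream of the TSS whose width depends on expression
  class (low 120 bp, neither 150 bp, high 300 bp), and a phased array
  also flanks the NDR on the upstream side (the −1 nucleosome and beyond,
  covering ~1.2 kb): an exclusion zone is only observable if its flanks
  are occupied, as real chromatin's are. Each nucleosome emits
  Poisson(30) fragments with N(0, 10²) midpoint jitter and N(0, 10²)
  length jitter; uniform background fragments (2 per kb) fall everywhere,
  including NDRs. Fragments that would straddle a contig edge are dropped
  (mapped fragments always lie within contigs). Nucleosome geometry is
  genotype-independent — the mutant's chromatin is wild-type-like by
  construction, which the seed-to-seed equivalence tests exploit.
* **Methylation**: cytosine sites are placed at density 0.02/bp on random
  strands. True rates are per feature class with precedence
  repeat > gene body > upstream > background (0.08 / 0.015 / 0.02 /
  0.005), all multiplied by 0.6 in the mutant; the control contig is
  fully unmethylated. Coverage is Poisson(20) and observed methylated
  counts are `Binomial(cov, r + (1 − r)(1 − c))` with conversion
  probability c = 0.99 — failed conversions read as spurious methylation
  on the unmethylated fraction only, which is exactly what the
  control-contig estimator measures. The class rates are calibrated to
  the calling rule: at ~20× coverage a single methylated read trips the
  inclusive 5% threshold, so per-site rates must be modest for
  per-feature percentages to land mid-range (as the real box plots do)
  rather than saturating at 100%.
* **Determinism**: a single root seed derives fixed, mutually independent
  substreams per generator (genome, counts, MNase × genotype,
  methylation × genotype), so consuming one generator never perturbs
  another and outputs are byte-identical across runs.

What the generator does **not** emulate: sequence composition (no FASTA;
cytosine sites are abstract positions), read-level artefacts (quality,
duplicates, mapping bias), isoforms and exon structure, remodeller-driven
differences in nucleosome organisation between genotypes, and any coupling
between a gene's methylation and its expression change. Tests passing on
this generator therefore show that the analyses recover planted structure
under the stated noise models — not that real libraries are free of the
artefacts listed above.

## Problem sizes

Test and acceptance runs use desk-scale genomes chosen as the smallest
sizes at which the targeted statistics are stable: ~520 genes
(≥ 500 phased arrays, ~8500 adjacent-dyad pairs) for repeat-length
recovery; 2000 genes × 2+2 replicates for the stratified fold-change
direction; ≥ 200 features per class for the methylation comparison; and a
10,000-cytosine control contig (~2 × 10⁵ read observations) for
conversion-rate QC, where the binomial standard error is ~0.02 percentage
points.
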