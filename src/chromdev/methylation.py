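"""Feature-level DNA-methylation analysis from per-cytosine bisulfite calls.

Covers bisulfite conversion-rate QC on an unmethylated control contig,
methylated-cytosine calling at the "at least 5% of mapped reads" rule,
aggregation of methylated-cytosine percentages over gene bodies, upstream
windows and repeats, and two-genotype comparison by Student's t-test.

The percentage denominator is the number of *covered* cytosines inside each
feature — the only denominator estimable from count data; both strands
contribute independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import FeatureIndex
from .records import (
    BoxplotSummary,
    CytosineRecord,
    ValidationError,
    boxplot_summary,
)

FEATURE_CLASSES = ("gene_body", "upstream", "repeat")


def estimate_conversion_rate(records: list[CytosineRecord], control_contig: str) -> float:
    """Pooled bisulfite conversion rate (%) from the control contig.

    100 × Σ unmeth / Σ (meth + unmeth) over all control-contig records — a
    micro-average over reads, not a per-cytosine average.
    """
    meth = unmeth = 0
    for r in records:
        if r.contig == control_contig:
            meth += r.meth_count
            unmeth += r.unmeth_count
    total = meth + unmeth
    if total == 0:
        raise ValidationError(f"no coverage on control contig {control_contig!r}")
    return 100.0 * unmeth / total


@dataclass(frozen=True)
class MethylationCall:
    """A covered cytosine with its methylated/unmethylated verdict."""

    record: CytosineRecord
    coverage: int
    fraction: float
    is_methylated: bool


def call_methylated(
    records: list[CytosineRecord],
    min_fraction: float = 0.05,
    min_coverage: int = 1,
) -> list[MethylationCall]:
    """Flag cytosines methylated in at least ``min_fraction`` of reads.

    The threshold is inclusive ("at least 5%"). Zero-coverage records are
    excluded from the output; ``min_coverage`` (default 1, i.e. no extra
    filter) guards the rule against very low coverage when raised.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValidationError("min_fraction must be in (0, 1]")
    if min_coverage < 1:
        raise ValidationError("min_coverage must be >= 1")
    out = []
    for r in records:
        cov = r.coverage
        if cov == 0:
            continue
        frac = r.meth_count / cov
        out.append(
            MethylationCall(
                record=r,
                coverage=cov,
                fraction=frac,
                is_methylated=cov >= min_coverage and frac >= min_fraction,
            )
        )
    return out


@dataclass(frozen=True)
class FeatureMethylation:
    """Percentage of methylated cytosines among covered cytosines in one
    feature instance."""

    feature_id: str
    feature_class: str
    n_covered: int
    n_methylated: int

    @property
    def percent_methylated(self) -> float:
        return 100.0 * self.n_methylated / self.n_covered


@dataclass
class AggregationResult:
    features: list[FeatureMethylation]
    n_features_excluded: int  # features with no covered cytosine

    def of_class(self, feature_class: str) -> list[FeatureMethylation]:
        return [f for f in self.features if f.feature_class == feature_class]

    def percents(self, feature_class: str) -> np.ndarray:
        return np.array([f.percent_methylated for f in self.of_class(feature_class)])


def aggregate_by_feature(
    calls: list[MethylationCall], index: FeatureIndex
) -> AggregationResult:
    """Tally covered and methylated cytosines per feature instance.

    Overlapping features each receive independent tallies; both strands
    count. Features with no covered cytosine are excluded and counted.
    1-based report positions are converted to the index's 0-based frame.
    """
    tallies: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        rec = call.record
        clen = index.contig_lengths.get(rec.contig)
        if clen is not None and rec.pos > clen:
            raise ValidationError(
                f"cytosine at {rec.contig}:{rec.pos} beyond contig length {clen}"
            )
        for membership in index.memberships(rec.contig, rec.pos - 1):
            t = tallies.setdefault(membership, [0, 0])
            t[0] += 1
            t[1] += int(call.is_methylated)
    features = []
    n_excluded = 0
    for f in index.features:
        t = tallies.get((f.feature_class, f.feature_id))
        if t is None:
            n_excluded += 1
            continue
        features.append(
            FeatureMethylation(
                feature_id=f.feature_id,
                feature_class=f.feature_class,
                n_covered=t[0],
                n_methylated=t[1],
            )
        )
    return AggregationResult(features=features, n_features_excluded=n_excluded)


@dataclass(frozen=True)
class ClassComparison:
    feature_class: str
    wt: BoxplotSummary
    mutant: BoxplotSummary
    mean_difference: float  # mutant − wild type
    t_statistic: float
    p_value: float
    degenerate: bool = False  # zero pooled variance


@dataclass
class GenotypeComparison:
    by_class: dict[str, ClassComparison]


def _two_sample_t(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test (pooled Student's or Welch).

    Zero-variance inputs are degenerate: t = 0, p = 1 when the means agree,
    otherwise p = 0 with infinite t (flagged, with a warning).
    """
    from scipy import stats

    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, 1.0, True
        warnings.warn("zero-variance t-test input; returning p = 0", stacklevel=3)
        return float(np.sign(my - mx)) * float("inf"), 0.0, True
    if welch:
        se2 = vx / nx + vy / ny
        t = (my - mx) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        t = (my - mx) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = nx + ny - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), False


def compare_genotypes(
    wt: AggregationResult | list[FeatureMethylation],
    mutant: AggregationResult | list[FeatureMethylation],
    welch: bool = False,
) -> GenotypeComparison:
    """Compare per-feature methylation percentages between genotypes.

    Per feature class present with >= 2 features in both genotypes: boxplot
    summaries, mean difference (mutant − wild type) and a two-sided
    two-sample t-test on the percentages. Classes absent or underpopulated
    in either genotype are skipped with a warning.
    """
    wt_feats = wt.features if isinstance(wt, AggregationResult) else wt
    mut_feats = mutant.features if isinstance(mutant, AggregationResult) else mutant
    by_class: dict[str, ClassComparison] = {}
    for cls in FEATURE_CLASSES:
        x = np.array([f.percent_methylated for f in wt_feats if f.feature_class == cls])
        y = np.array([f.percent_methylated for f in mut_feats if f.feature_class == cls])
        if len(x) < 2 or len(y) < 2:
            if len(x) or len(y):
                warnings.warn(f"class {cls!r} underpopulated; skipped", stacklevel=2)
            continue
        t, p, degenerate = _two_sample_t(x, y, welch=welch)
        by_class[cls] = ClassComparison(
            feature_class=cls,
            wt=boxplot_summary(x),
            mutant=boxplot_summary(y),
            mean_difference=float(y.mean() - x.mean()),
            t_statistic=t,
            p_value=p,
            degenerate=degenerate,
        )
    return GenotypeComparison(by_class=by_class)


def methylation_by_expression_class(
    calls: list[MethylationCall],
    index: FeatureIndex,
    classes: dict[str, str],
    region: str = "gene_body",
) -> dict[str, AggregationResult]:
    """Aggregate one gene-linked region, stratified by expression class.

    ``region`` is ``gene_body`` or ``upstream``; feature ids of those
    regions are gene ids, so each expression class selects its genes'
    features. Exclusion counts are per class.
    """
    if region not in ("gene_body", "upstream"):
        raise ValidationError(f"region must be gene_body or upstream, got {region!r}")
    if not classes:
        raise ValidationError("empty expression-class mapping")
    agg = aggregate_by_feature(calls, index)
    covered = {f.feature_id: f for f in agg.features if f.feature_class == region}
    region_ids = {f.feature_id for f in index.features if f.feature_class == region}
    out: dict[str, AggregationResult] = {}
    for label in sorted(set(classes.values())):
        gene_ids = [g for g, lab in classes.items() if lab == label]
        if not gene_ids:
            raise ValidationError(f"empty expression class {label!r}")
        feats = [covered[g] for g in gene_ids if g in covered]
        n_excluded = sum(1 for g in gene_ids if g in region_ids and g not in covered)
        out[label] = AggregationResult(features=feats, n_features_excluded=n_excluded)
    return out
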