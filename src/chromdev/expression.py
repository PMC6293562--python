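"""Expression-level analyses: RPKM, median-of-ratios size factors, log2
fold changes with MA coordinates, expression-class stratification, and
sample correlation clustering.

Differential-expression significance testing is deliberately out of scope;
the stratified fold-change distributions here are distributional summaries
over all genes (optionally restricted to a caller-supplied gene list).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .records import BoxplotSummary, CountTable, ValidationError, boxplot_summary


def compute_rpkm(table: CountTable) -> pd.DataFrame:
    """Reads per kilobase per million counted reads.

    RPKM[g, j] = 1e9 * count[g, j] / (length[g] * library_size[j]), with
    library size the column sum of counted reads.
    """
    lib = table.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValidationError(f"zero library size for samples: {bad}")
    lengths = table.gene_lengths.astype(float)
    return 1e9 * table.counts.div(lib, axis=1).div(lengths, axis=0)


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios (DESeq-style) per-sample size factors.

    factor_j = median over genes with counts > 0 in every sample of
    count[g, j] / geometric_mean_g.
    """
    counts = table.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValidationError("no gene has nonzero counts in all samples")
    sub = counts[all_nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold change (mutant vs wild type) and MA x-coordinate."""

    table: pd.DataFrame  # columns: log2fc, mean_norm; index: gene ids

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def mean_norm(self) -> pd.Series:
        return self.table["mean_norm"]


def log2_fold_change(
    table: CountTable,
    factors: pd.Series,
    group_mut: list[str],
    group_wt: list[str],
    pseudocount: float = 0.5,
) -> FoldChangeTable:
    """Per-gene log2((mean normalized mutant + pc) / (mean normalized wt + pc)).

    The MA x-coordinate is the mean of all samples' normalized counts.
    """
    if not group_mut or not group_wt:
        raise ValidationError("both sample groups must be non-empty")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    norm = table.counts.div(factors, axis=1)
    m_mut = norm[group_mut].mean(axis=1)
    m_wt = norm[group_wt].mean(axis=1)
    out = pd.DataFrame(
        {
            "log2fc": np.log2((m_mut + pseudocount) / (m_wt + pseudocount)),
            "mean_norm": norm.mean(axis=1),
        }
    )
    return FoldChangeTable(out)


def classify_by_wt_rpkm(
    rpkm: pd.DataFrame,
    wt_samples: list[str],
    low_max: float = 1.0,
    high_min: float = 5.0,
) -> pd.Series:
    """Expression classes from mean wild-type RPKM: strictly below ``low_max``
    → low, strictly above ``high_min`` → high, otherwise neither."""
    if low_max > high_min:
        raise ValidationError("low_max must be <= high_min")
    mean_wt = rpkm[wt_samples].mean(axis=1)
    cls = np.where(mean_wt < low_max, "low", np.where(mean_wt > high_min, "high", "neither"))
    return pd.Series(cls, index=rpkm.index, name="expr_class")


def fold_change_distribution(
    fc: FoldChangeTable, classes: pd.Series, expr_class: str
) -> BoxplotSummary:
    """Boxplot summary of log2 fold changes within one expression class."""
    values = fc.log2fc[classes.reindex(fc.table.index) == expr_class]
    if values.empty:
        raise ValidationError(f"no genes in class {expr_class!r}")
    return boxplot_summary(values.to_numpy())


@dataclass
class CorrelationResult:
    """Sample × sample Spearman correlations with a dendrogram leaf order."""

    corr: pd.DataFrame
    leaf_order: list[str]
    n_genes_used: int


def sample_correlation_clustering(rpkm: pd.DataFrame) -> CorrelationResult:
    """Spearman correlation of log2 RPKM over genes measured in all samples,
    with average-linkage clustering on distance 1 − ρ.

    Samples are processed in lexicographic id order so the leaf order is
    deterministic, including under correlation ties.
    """
    if rpkm.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    cols = sorted(rpkm.columns)
    mat = rpkm[cols]
    keep = (mat > 0).all(axis=1)
    if int(keep.sum()) < 2:
        raise ValidationError("fewer than 2 genes measured in all samples")
    logm = np.log2(mat[keep].to_numpy())
    rho = spearmanr(logm, axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two samples: spearmanr returns a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [cols[i] for i in hierarchy.leaves_list(link)]
    corr = pd.DataFrame(rho, index=cols, columns=cols)
    return CorrelationResult(corr=corr, leaf_order=order, n_genes_used=int(keep.sum()))
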