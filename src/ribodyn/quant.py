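"""Region-level quantification and time-course statistics.

RPKM, translation efficiency (Ribo-seq CDS density over RNA-seq CDS
density), the 5'UTR/CDS upstream-translation ratio, per-gene z-score
profiles across timepoints, and ANOVA-gated hierarchical clustering of
time courses into k groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests


def rpkm(count: float, feature_len_nt: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_len_nt <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (feature_len_nt / 1e3) / (library_size / 1e6)


def translation_efficiency(
    ribo_rpkm: float, rna_rpkm: float, min_rna_rpkm: float = 1.0
) -> float:
    """TE = Ribo-seq RPKM / RNA-seq RPKM on the CDS.

    Returns NaN when RNA abundance is below ``min_rna_rpkm`` (ratio would
    be dominated by noise).
    """
    if rna_rpkm < min_rna_rpkm or rna_rpkm <= 0:
        return float("nan")
    return ribo_rpkm / rna_rpkm


def upstream_ratio(ribo_utr5_count: float, ribo_cds_count: float) -> float:
    """Ratio of footprint reads in the 5'UTR over reads in the CDS."""
    if ribo_cds_count <= 0:
        return float("nan")
    return ribo_utr5_count / ribo_cds_count


def label_upstream_tertiles(
    delta_ratio: pd.Series, fraction: float = 0.3
) -> pd.Series:
    """Label genes by change in upstream-translation ratio.

    The top ``fraction`` of genes by change get ``"High"``, the bottom
    ``fraction`` get ``"Low"``, the middle ``"Mid"``.  Ties are broken by
    gene id so labels are deterministic.
    """
    clean = delta_ratio.dropna()
    order = clean.iloc[np.lexsort((clean.index.astype(str), clean.values))]
    n = len(order)
    k = int(math.floor(n * fraction))
    labels = pd.Series("Mid", index=order.index, dtype=object)
    if k:
        labels.iloc[:k] = "Low"
        labels.iloc[n - k :] = "High"
    return labels.reindex(delta_ratio.index)


def zscore_profile(values: np.ndarray | pd.Series) -> np.ndarray | None:
    """Z-score a gene's expression across timepoints with sample (n-1) SD.

    Returns ``None`` for constant profiles (zero SD), which are excluded
    from clustering.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two timepoints")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - x.mean()) / sd


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ClusterResult:
    """Per-gene ANOVA statistics and cluster labels for significant genes."""

    table: pd.DataFrame  # columns: anova_F, anova_p, fdr_q, cluster (NaN if not clustered)
    zscores: pd.DataFrame  # z-scored timepoint means of clustered genes


def anova_timecourse(
    matrix: pd.DataFrame,
    k: int = 6,
    fdr_threshold: float = 0.05,
) -> ClusterResult:
    """ANOVA-gated time-course clustering.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples, with a two-level column MultiIndex
        ``(timepoint, replicate)``.  Replicates stay separate for the
        one-way ANOVA across timepoints and are averaged per timepoint
        before z-scoring and clustering.
    k : int
        Number of clusters to cut the Ward tree into.

    Genes whose BH-adjusted ANOVA p-value falls below ``fdr_threshold``
    are z-scored across timepoint means and clustered with Ward linkage
    on Euclidean distance.
    """
    if not isinstance(matrix.columns, pd.MultiIndex):
        raise ValueError("matrix needs (timepoint, replicate) MultiIndex columns")
    timepoints = matrix.columns.get_level_values(0)
    groups = [matrix.loc[:, timepoints == tp].to_numpy() for tp in pd.unique(timepoints)]
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("need at least two replicates per timepoint")

    F, p = _vectorized_f_oneway(groups)
    valid = np.isfinite(F) & np.isfinite(p)
    q = np.full_like(p, np.nan)
    q[valid] = bh_fdr(p[valid])

    table = pd.DataFrame(
        {"anova_F": F, "anova_p": p, "fdr_q": q, "cluster": np.nan},
        index=matrix.index,
    )

    means = matrix.T.groupby(level=0).mean().T  # genes x timepoints
    sig = table.index[valid & (q < fdr_threshold)]
    zrows, zindex = [], []
    for gene in sig:
        z = zscore_profile(means.loc[gene].to_numpy())
        if z is not None:
            zrows.append(z)
            zindex.append(gene)
    if len(zindex) >= k:
        Z = np.vstack(zrows)
        linkage = hierarchy.linkage(Z, method="ward")
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        table.loc[zindex, "cluster"] = labels
        zdf = pd.DataFrame(Z, index=zindex, columns=pd.unique(timepoints))
    else:
        zdf = pd.DataFrame(columns=pd.unique(timepoints))
    return ClusterResult(table=table, zscores=zdf)


def _vectorized_f_oneway(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA F and p per row, matching scipy.stats.f_oneway."""
    ns = np.array([g.shape[1] for g in groups])
    N = ns.sum()
    kk = len(groups)
    grand = np.hstack(groups).mean(axis=1, keepdims=True)
    means = np.column_stack([g.mean(axis=1) for g in groups])
    ss_between = (ns * (means - grand) ** 2).sum(axis=1)
    ss_within = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in
                    zip(groups, [g.mean(axis=1) for g in groups]))
    df_b, df_w = kk - 1, N - kk
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    # zero within-variance with equal means: F is 0/0, undefined
    degenerate = (ss_within == 0) & (ss_between == 0)
    F[degenerate] = np.nan
    p[degenerate] = np.nan
    return F, p
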