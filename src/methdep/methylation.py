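"""Locus-level CpG analysis: correlation clustering, thresholds, summaries.

CpG sites within a locus are clustered on the distance 1 - r (pairwise
Pearson correlation across samples) with agglomerative linkage and a fixed
tree cut, which recovers tightly co-methylated blocks without assuming a
cluster count. Clusters whose mean beta is below 0.1 are flagged uniformly
lowly methylated and excluded from biomarker candidacy. Beta values are
binarized at a configurable cutoff (methylated iff beta >= cutoff), and the
cutoff itself can be chosen by scanning a candidate grid with two-sided
exact tests against sensitivity labels; the scan reports uncorrected
per-cutoff p-values and is explicitly exploratory (selection over cutoffs
is not corrected).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .biomarker import single_correlate
from .stats import FisherResult, fisher_exact_2x2  # re-exported; shared 2x2 primitive

__all__ = [
    "ClusterAssignment",
    "ThresholdScanResult",
    "locus_submatrix",
    "cluster_cpg_sites",
    "correlate_sites_with_response",
    "binarize_methylation",
    "scan_threshold",
    "fisher_exact_2x2",
    "FisherResult",
    "summarize_age_methylation",
]

logger = logging.getLogger(__name__)

BETA_CUTOFF = 0.5
LOW_METHYLATION_MEAN = 0.1
CLUSTER_CUT_HEIGHT = 0.5
DEFAULT_CUTOFF_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
AGE_CUTOFF = 21


@dataclass
class ClusterAssignment:
    """CpG -> cluster label with per-cluster summaries.

    ``low_methylation`` flags clusters with mean beta below the exclusion
    threshold; ``candidate_sites`` lists the CpGs of non-excluded clusters.
    """

    labels: pd.Series  # cpg_id -> int label
    cluster_means: pd.Series  # label -> mean beta
    low_methylation: pd.Series  # label -> bool
    cut_height: float
    linkage_method: str

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def candidate_sites(self) -> list[str]:
        good = self.low_methylation.index[~self.low_methylation]
        return list(self.labels.index[self.labels.isin(good)])


@dataclass
class ThresholdScanResult:
    table: pd.DataFrame  # per-cutoff 2x2 counts, p, odds ratio, degenerate flag
    chosen_cutoff: float


def locus_submatrix(
    methylation: pd.DataFrame, annotation: pd.DataFrame, locus: str
) -> pd.DataFrame:
    """Rows of the beta matrix mapping to one locus, original order kept."""
    annotation = annotation.reindex(methylation.index)
    available = sorted(annotation["locus"].dropna().unique())
    if locus not in available:
        raise ValueError(f"locus {locus!r} not found; available loci: {available}")
    mask = (annotation["locus"] == locus).to_numpy()
    return methylation.loc[mask]


def cluster_cpg_sites(
    sub: pd.DataFrame,
    linkage: str = "average",
    cut_height: float = CLUSTER_CUT_HEIGHT,
    low_methylation_mean: float = LOW_METHYLATION_MEAN,
) -> ClusterAssignment:
    """Agglomerative clustering of CpG sites on correlation distance.

    Distance between sites is 1 - Pearson r of their beta values across
    samples; a constant site has correlation 0 with everything (logged).
    The tree is cut at ``cut_height`` so sites joining below that distance
    share a label. Output labels are renumbered in order of first
    appearance so they are invariant to row order.
    """
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 CpG sites to cluster")
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant CpG rows (correlation defined as 0): %s",
            list(sub.index[constant]),
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)

    Z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    raw_labels = fcluster(Z, t=cut_height, criterion="distance")

    # renumber by first appearance under a canonical (sorted) row order so
    # labels do not depend on input row order
    order = np.argsort(sub.index.to_numpy())
    remap: dict[int, int] = {}
    for pos in order:
        remap.setdefault(raw_labels[pos], len(remap) + 1)
    labels = pd.Series(
        [remap[l] for l in raw_labels], index=sub.index, name="cluster"
    )
    cluster_means = sub.groupby(labels).apply(lambda block: float(block.to_numpy().mean()))
    cluster_means.index.name = "cluster"
    low = cluster_means < low_methylation_mean
    return ClusterAssignment(
        labels=labels,
        cluster_means=cluster_means,
        low_methylation=low,
        cut_height=cut_height,
        linkage_method=linkage,
    )


def correlate_sites_with_response(sub: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    """Waterfall: per-CpG Pearson r against the response, signed ascending.

    The most negative correlation (strongest sensitivity association when
    the response is AUC) comes first. Statistics delegate to
    :func:`methdep.biomarker.single_correlate`.
    """
    df = single_correlate(sub.T, response)
    return df.sort_values(["pearson_r", "feature"], kind="mergesort")


def binarize_methylation(values, cutoff: float = BETA_CUTOFF):
    """Label beta values 'methylated' (beta >= cutoff, inclusive) or not."""
    if isinstance(values, pd.Series):
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    labels = np.where(arr >= cutoff, "methylated", "unmethylated")
    if isinstance(values, pd.Series):
        return pd.Series(labels, index=values.index, name="methylation_call")
    return labels


def scan_threshold(
    values: pd.Series,
    labels: pd.Series,
    candidates=DEFAULT_CUTOFF_GRID,
) -> ThresholdScanResult:
    """Choose a binarization cutoff by exact-test scanning.

    For each candidate cutoff the 2x2 table (methylated/unmethylated x
    sensitive/resistant) is tested two-sided; cutoffs that empty one
    methylation row are degenerate and recorded with p = 1. The chosen
    cutoff attains minimal p, ties resolved toward the smallest cutoff.
    P-values are uncorrected for the selection over cutoffs; treat the scan
    as exploratory.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("candidate grid must be nonempty")
    labels = labels.reindex(values.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    counts = labels.value_counts()
    if set(counts.index) - {"sensitive", "resistant"}:
        raise ValueError("labels must be 'sensitive'/'resistant'")
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each response class")

    sens = (labels == "sensitive").to_numpy()
    beta = values.to_numpy(dtype=float)
    rows = []
    for cutoff in np.sort(candidates):
        meth = beta >= cutoff
        a = int((meth & sens).sum())
        b = int((meth & ~sens).sum())
        c = int((~meth & sens).sum())
        d = int((~meth & ~sens).sum())
        degenerate = (a + b == 0) or (c + d == 0)
        if degenerate:
            p, odds = 1.0, float("nan")
        else:
            res = fisher_exact_2x2([[a, b], [c, d]])
            p, odds = res.p_value, res.odds_ratio
        rows.append((cutoff, a, b, c, d, p, odds, degenerate))
    table = pd.DataFrame(
        rows,
        columns=[
            "cutoff",
            "n_methylated_sensitive",
            "n_methylated_resistant",
            "n_unmethylated_sensitive",
            "n_unmethylated_resistant",
            "p_value",
            "odds_ratio",
            "degenerate",
        ],
    ).set_index("cutoff")
    chosen = float(table["p_value"].idxmin())  # idxmin takes first == smallest cutoff
    logger.info(
        "threshold scan chose cutoff %.3g (uncorrected p = %.3g; exploratory)",
        chosen,
        table.loc[chosen, "p_value"],
    )
    return ThresholdScanResult(table=table, chosen_cutoff=chosen)


def summarize_age_methylation(
    methylation: pd.DataFrame,
    site_set,
    ages: pd.Series,
    age_cutoff: float = AGE_CUTOFF,
    statistic: str = "mean_over_sites",
) -> dict:
    """Per-sample methylation summary compared between age groups.

    ``statistic`` is either the mean beta over ``site_set`` or the median
    beta over all CpGs ('global_median'). Samples with age below the cutoff
    are pediatric. Groups are compared with an unpaired two-sided Student's
    t-test; each group needs at least 2 samples.
    """
    site_set = list(site_set)
    if statistic == "mean_over_sites":
        if len(site_set) == 0:
            raise ValueError("site_set must be nonempty for mean_over_sites")
        missing = set(site_set) - set(methylation.index)
        if missing:
            raise ValueError(f"unknown CpG sites: {sorted(missing)}")
        summary = methylation.loc[site_set].mean(axis=0)
    elif statistic == "global_median":
        summary = methylation.median(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    summary.name = statistic

    ages = ages.reindex(summary.index)
    if ages.isna().any():
        raise ValueError("ages missing for some samples")
    pediatric = summary[ages < age_cutoff]
    adult = summary[ages >= age_cutoff]
    if len(pediatric) < 2 or len(adult) < 2:
        raise ValueError("need at least 2 samples per age group for the t-test")
    t_stat, p = sps.ttest_ind(pediatric, adult, equal_var=True)
    return {
        "summary": summary,
        "statistic": statistic,
        "age_cutoff": age_cutoff,
        "n_pediatric": int(len(pediatric)),
        "n_adult": int(len(adult)),
        "mean_pediatric": float(pediatric.mean()),
        "mean_adult": float(adult.mean()),
        "t_stat": float(t_stat),
        "p_value": float(p),
    }
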