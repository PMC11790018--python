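"""Pooled CRISPR screen analysis: counts to gene dependency scores.

The dependency score (beta) for a gene in a cell line is the median, over
its guides, of replicate-averaged log2 fold-changes of endpoint abundance
versus the day-0 reference, affinely rescaled per cell line so that the
median nontargeting-control gene scores 0 and the median core-essential
control gene scores -1. More negative beta means a stronger growth
dependency. The module also provides screen QC, hit calling, two-group
differential dependency testing with Benjamini-Hochberg adjustment,
prevalence contingency analysis, and per-model gene ranking.

Gene aggregation is a deliberate simplification relative to
regression-based essentiality estimators: the median of guide-level
fold-changes is robust, fully specified, and recoverable against planted
truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, fisher_exact_2x2, percent_display

logger = logging.getLogger(__name__)

HIT_TAU = -0.5
DELTA_GATE = 0.1
FDR_LEVEL = 0.05

ROLES = ("target", "essential_control", "nontargeting_control")


@dataclass
class BetaScoreTable:
    """Gene x cell-line dependency scores with the per-line anchoring record."""

    scores: pd.DataFrame  # gene x cell_line, control-anchored
    anchoring: pd.DataFrame  # cell_line-indexed: nontargeting_center, essential_center
    roles: pd.Series  # gene -> role

    def targets(self) -> pd.DataFrame:
        return self.scores.loc[self.roles[self.roles == "target"].index]


@dataclass
class QCReport:
    replicate_correlations: pd.DataFrame  # cell_line, replicate_a, replicate_b, pearson_r
    representation: pd.DataFrame  # sample_id-indexed fraction_represented
    passed: bool | None  # None when no replicate pair exists
    warnings: list[str] = field(default_factory=list)


def validate_library(library: pd.DataFrame) -> None:
    if library.index.duplicated().any():
        dup = library.index[library.index.duplicated()][0]
        raise ValueError(f"duplicate guide_id in library: {dup!r}")
    bad = set(library["role"].unique()) - set(ROLES)
    if bad:
        raise ValueError(f"unknown guide roles: {sorted(bad)}")
    per_gene = library[library["role"] == "target"].groupby("gene").size()
    if (per_gene < 2).any():
        gene = per_gene[per_gene < 2].index[0]
        raise ValueError(f"target gene {gene!r} has fewer than 2 guides")
    for role in ("essential_control", "nontargeting_control"):
        if (library["role"] == role).sum() < 1:
            raise ValueError(f"library has no {role} guides")


def normalize_counts(
    counts: pd.DataFrame, pseudocount: float = 1.0, per_million: bool = True
) -> pd.DataFrame:
    """Log2 of depth-normalized counts.

    Per-sample counts are scaled to a common total (counts-per-million when
    ``per_million``), the pseudocount is added and log2 taken. Column sums on
    the linear scale are equal across samples before the log.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    if per_million:
        scaled = counts / totals * 1e6
    else:
        scaled = counts.astype(float)
    return np.log2(scaled + pseudocount)


def compute_beta_scores(
    norm: pd.DataFrame, samples: pd.DataFrame, library: pd.DataFrame
) -> BetaScoreTable:
    """Gene-level, control-anchored dependency scores per cell line.

    Each endpoint sample is compared against its cell line's own day-0
    reference samples when present, otherwise against the shared (plasmid)
    reference pool. Guide log2 fold-changes are averaged over replicates,
    genes aggregated by the median across guides, and each cell line's gene
    scores affinely mapped so the nontargeting-gene median is 0 and the
    essential-control-gene median is -1.
    """
    validate_library(library)
    missing = library.index.difference(norm.index)
    if len(missing) > 0:
        raise ValueError(f"normalized matrix missing library guide {missing[0]!r}")

    ref_mask = samples["timepoint"] == "day0_reference"
    if not ref_mask.any():
        raise ValueError("no day0_reference samples present")
    ref_all = norm[samples.index[ref_mask]].mean(axis=1)

    gene_of_guide = library["gene"]
    roles = library.drop_duplicates("gene").set_index("gene")["role"]

    endpoint = samples[samples["timepoint"] == "endpoint"]
    scores: dict[str, pd.Series] = {}
    anchors: list[tuple[str, float, float]] = []
    for cell_line, meta in endpoint.groupby("cell_line"):
        own_ref_ids = samples.index[ref_mask & (samples["cell_line"] == cell_line)]
        ref = norm[own_ref_ids].mean(axis=1) if len(own_ref_ids) > 0 else ref_all
        lfc = norm[meta.index].sub(ref, axis=0).mean(axis=1)
        gene_score = lfc.loc[library.index].groupby(gene_of_guide).median()

        m_nt = gene_score[roles[gene_score.index] == "nontargeting_control"].median()
        m_ess = gene_score[roles[gene_score.index] == "essential_control"].median()
        if np.isclose(m_nt, m_ess):
            raise ValueError(
                f"degenerate anchoring for cell line {cell_line!r}: "
                f"nontargeting and essential medians coincide ({m_nt:.4g})"
            )
        scores[cell_line] = (gene_score - m_nt) / (m_nt - m_ess)
        anchors.append((cell_line, float(m_nt), float(m_ess)))

    score_df = pd.DataFrame(scores)
    score_df.index.name = "gene"
    anchoring = pd.DataFrame(
        anchors, columns=["cell_line", "nontargeting_center", "essential_center"]
    ).set_index("cell_line")
    return BetaScoreTable(scores=score_df, anchoring=anchoring, roles=roles)


def qc_screen(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    floor: int = 30,
    pseudocount: float = 1.0,
) -> QCReport:
    """Replicate correlations and guide representation.

    Pearson correlation of log-normalized guide counts is computed for every
    replicate pair within a (cell line, timepoint); the screen passes when
    all pairs exceed 0.5. Representation is the fraction of guides with raw
    count at or above ``floor`` in each sample.
    """
    warnings: list[str] = []
    norm = normalize_counts(counts, pseudocount=pseudocount)
    representation = (counts >= floor).mean(axis=0).rename("fraction_represented")
    representation.index.name = "sample_id"

    rows = []
    for (cell_line, timepoint), meta in samples.groupby(["cell_line", "timepoint"]):
        ids = list(meta.index)
        if len(ids) < 2:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = float(np.corrcoef(norm[ids[i]], norm[ids[j]])[0, 1])
                rows.append((cell_line, ids[i], ids[j], r))
    correlations = pd.DataFrame(
        rows, columns=["cell_line", "replicate_a", "replicate_b", "pearson_r"]
    )
    if correlations.empty:
        warnings.append("no replicate pairs available; correlations omitted")
        logger.warning(warnings[-1])
        passed: bool | None = None
    else:
        passed = bool((correlations["pearson_r"] > 0.5).all())
    return QCReport(
        replicate_correlations=correlations,
        representation=representation.to_frame(),
        passed=passed,
        warnings=warnings,
    )


def call_hits(betas: BetaScoreTable | pd.DataFrame, tau: float = HIT_TAU) -> pd.DataFrame:
    """Boolean gene x cell-line hit matrix: hit iff beta <= tau (inclusive)."""
    scores = betas.scores if isinstance(betas, BetaScoreTable) else betas
    return scores <= tau


def differential_dependency(
    betas: BetaScoreTable | pd.DataFrame,
    groups: pd.Series,
    group_a: str = "adult",
    group_b: str = "pediatric",
    delta_gate: float = DELTA_GATE,
    fdr_level: float = FDR_LEVEL,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group comparison of dependency scores.

    An unpaired two-sided t-test (Student's by default, Welch with
    ``equal_var=False``) is run per gene; p-values are Benjamini-Hochberg
    adjusted across all tested genes. ``delta`` is mean(group_a) -
    mean(group_b), so with the adult/pediatric defaults a positive delta
    means a stronger pediatric dependency. Calls require both the delta gate
    and FDR significance. Genes with zero variance in both groups are
    reported with p = 1 and flagged rather than raising.
    """
    if isinstance(betas, BetaScoreTable):
        scores = betas.targets()
    else:
        scores = betas
    groups = groups.reindex(scores.columns)
    if groups.isna().any():
        missing = groups.index[groups.isna()][0]
        raise ValueError(f"cell line {missing!r} has no group label")
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both groups need at least 2 cell lines")

    a = scores[a_cols].to_numpy(dtype=float)
    b = scores[b_cols].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(p)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 1.0, p)
    fdr = bh_adjust(p)

    call = np.full(len(scores), "none", dtype=object)
    call[(delta >= delta_gate) & (fdr < fdr_level)] = "pediatric_specific"
    call[(delta <= -delta_gate) & (fdr < fdr_level)] = "adult_specific"

    return pd.DataFrame(
        {
            "mean_beta_adult": mean_a,
            "mean_beta_pediatric": mean_b,
            "delta": delta,
            "t_stat": t_stat,
            "p_value": p,
            "fdr": fdr,
            "call": call,
            "degenerate": degenerate,
        },
        index=scores.index,
    )


def dependency_prevalence(
    hits: pd.Series,
    groups: pd.Series,
    group_order: tuple[str, str] = ("pediatric", "adult"),
) -> dict:
    """Per-group hit prevalence and a two-sided exact test on the 2x2 table.

    ``hits`` is a boolean per cell line (one gene's calls). Percentages are
    rounded half-up to integers for display; the exact test delegates to
    :func:`methdep.stats.fisher_exact_2x2`.
    """
    groups = groups.reindex(hits.index)
    if groups.isna().any():
        raise ValueError("every cell line in hits needs a group label")
    table = []
    counts = {}
    percents = {}
    for g in group_order:
        members = hits[groups == g]
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        k = int(members.sum())
        n = int(len(members))
        table.append([k, n - k])
        counts[g] = (k, n)
        percents[g] = percent_display(k, n)
    result = fisher_exact_2x2(table)
    return {
        "counts": counts,
        "percent": percents,
        "table": np.asarray(table),
        "p_value": result.p_value,
        "odds_ratio": result.odds_ratio,
    }


def rank_genes(
    betas: BetaScoreTable | pd.DataFrame,
    cell_line: str,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Genes ordered by ascending dependency score for one cell line.

    Rank 1 is the strongest (most negative) dependency; ties break
    lexicographically by gene id.
    """
    if isinstance(betas, BetaScoreTable):
        scores = betas.scores if include_controls else betas.targets()
    else:
        scores = betas
    if cell_line not in scores.columns:
        raise ValueError(f"unknown cell line {cell_line!r}")
    col = scores[cell_line]
    ordered = col.iloc[np.lexsort((col.index.to_numpy(), col.to_numpy()))]
    out = ordered.to_frame("beta")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
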