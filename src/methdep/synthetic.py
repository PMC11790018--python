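"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure a pharmaco-epigenomic dependency analysis
assumes: a panel of pediatric and adult tumor cell lines in which a latent
binary methylation state at one CpG cluster drives (i) a tightly
co-methylated 10-site block inside a 44-CpG locus, (ii) anti-correlated
expression of the host gene, (iii) an age-group-specific genetic dependency
visible in pooled CRISPR screen counts, and (iv) sensitivity to a targeted
inhibitor in 12-point dose-response assays.

Every generator draws from a single :class:`numpy.random.Generator` seeded
from ``TruthConfig.seed``, so identical configurations reproduce identical
tables. The planted parameters are returned in a :class:`SyntheticTruth`
object against which estimator-recovery tests compare each analysis stage.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError

logger = logging.getLogger(__name__)

UM_TO_NM = 1000.0

#: Cohort-wide locus/drug naming. The focal dependency gene and its
#: methylation-marked partner locus mirror the anti-apoptotic pairing the
#: analysis is designed around; the names are labels only.
FOCAL_GENE = "MCL1"
LOCUS_GENE = "BCL2L1"
DRUG_NAME = "AZD5991"


def default_dose_grid() -> tuple[float, ...]:
    """Zero plus 11 half-log-spaced concentrations up to 20 uM."""
    return (0.0,) + tuple(20.0 * 10 ** (-0.5 * k) for k in range(10, -1, -1))


@dataclass(frozen=True)
class LibrarySpec:
    """Layout of the pooled sgRNA knockout library.

    Defaults follow a targeted oncology library: 352 target genes at
    4 guides per gene, 62 core-essential positive-control genes, and 250
    nontargeting guides split across 2 negative-control pseudo-genes.
    """

    n_target_genes: int = 352
    guides_per_gene: int = 4
    n_essential_genes: int = 62
    essential_guides_per_gene: int = 4
    n_nontargeting_guides: int = 250
    n_nontargeting_genes: int = 2

    @property
    def n_guides(self) -> int:
        return (
            self.n_target_genes * self.guides_per_gene
            + self.n_essential_genes * self.essential_guides_per_gene
            + self.n_nontargeting_guides
        )


def _default_planted_beta() -> dict[tuple[str, bool], float]:
    # Methylated pediatric lines carry the strong dependency; everything else
    # sits at the weak adult-level effect.
    return {
        ("pediatric", True): -0.92,
        ("pediatric", False): -0.18,
        ("adult", True): -0.18,
        ("adult", False): -0.18,
    }


@dataclass(frozen=True)
class TruthConfig:
    """All planted parameters of a synthetic cohort.

    Methylation values are drawn from beta distributions: the methylated and
    unmethylated cluster states use shape pairs that are mirror images of
    each other so their densities cross at beta = 0.5, which realizes the
    0.5 binarization threshold as the genuinely optimal separator. A third
    shape pair generates uniformly lowly methylated sites (column mean
    < 0.1) emulating the excluded low-methylation cluster.
    """

    # cohort composition
    n_pediatric: int = 65
    n_adult: int = 10
    p_methylated_pediatric: float = 0.75
    p_methylated_adult: float = 0.10

    # methylation locus layout
    n_locus_cpgs: int = 44
    cluster_size: int = 10
    n_low_locus_cpgs: int = 12
    n_background_cpgs: int = 300
    beta_high_params: tuple[float, float] = (64.0, 35.0)
    beta_low_params: tuple[float, float] = (35.0, 64.0)
    low_site_beta_params: tuple[float, float] = (1.5, 20.0)
    site_jitter_sd: float = 0.05

    # expression
    n_genes_expression: int = 300
    expr_methylation_slope: float = 2.0
    expr_noise_sd: float = 0.5
    target_expr_corr: float | None = -0.87

    # other omics blocks
    n_mutation_genes: int = 25
    n_cnv_genes: int = 15
    binary_event_rate: float = 0.1

    # CRISPR screen
    library_spec: LibrarySpec = field(default_factory=LibrarySpec)
    planted_beta: dict[tuple[str, bool], float] = field(
        default_factory=_default_planted_beta
    )
    background_effect_sd: float = 0.4
    guide_jitter_sd: float = 0.1
    sequencing_depth: float | None = None  # reads/sample; None -> 500x coverage
    target_coverage: float = 500.0  # mean reads per guide when depth unset
    dispersion: float = 0.05
    plasmid_dispersion: float = 0.005
    n_screen_replicates: int = 2

    # dose response
    dose_grid: tuple[float, ...] = field(default_factory=default_dose_grid)
    n_dose_replicates: int = 3
    hill: float = 1.0
    ic50_methylated_log10nM_mean: float = 2.6
    ic50_methylated_log10nM_sd: float = 0.35
    resistant_ic50_floor_uM: float = 50.0
    viability_noise_sd: float = 0.05

    seed: int = 0

    @property
    def reads_per_guide(self) -> float:
        if self.sequencing_depth is not None:
            return self.sequencing_depth / self.library_spec.n_guides
        return self.target_coverage

    def replace(self, **changes) -> "TruthConfig":
        return replace(self, **changes)


def validate_config(config: TruthConfig) -> None:
    """Raise :class:`ConfigError` naming the first invalid field."""

    def _count(name, value, minimum=0):
        if not isinstance(value, (int, np.integer)) or value < minimum:
            raise ConfigError(f"{name} must be an integer >= {minimum}, got {value!r}")

    def _prob(name, value):
        if not (0.0 <= value <= 1.0):
            raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")

    def _positive(name, value):
        if not (np.isfinite(value) and value > 0):
            raise ConfigError(f"{name} must be positive and finite, got {value!r}")

    _count("n_pediatric", config.n_pediatric)
    _count("n_adult", config.n_adult)
    if config.n_pediatric + config.n_adult < 1:
        raise ConfigError("n_pediatric + n_adult must be at least 1")
    _prob("p_methylated_pediatric", config.p_methylated_pediatric)
    _prob("p_methylated_adult", config.p_methylated_adult)
    _prob("binary_event_rate", config.binary_event_rate)
    _count("n_locus_cpgs", config.n_locus_cpgs, minimum=1)
    _count("cluster_size", config.cluster_size)
    _count("n_low_locus_cpgs", config.n_low_locus_cpgs)
    if config.cluster_size + config.n_low_locus_cpgs > config.n_locus_cpgs:
        raise ConfigError(
            "cluster_size + n_low_locus_cpgs must not exceed n_locus_cpgs"
        )
    _count("n_background_cpgs", config.n_background_cpgs)
    for name in ("beta_high_params", "beta_low_params", "low_site_beta_params"):
        pair = getattr(config, name)
        if len(pair) != 2 or any(not (p > 0) for p in pair):
            raise ConfigError(f"{name} must be a pair of positive shapes, got {pair!r}")
    if config.site_jitter_sd < 0:
        raise ConfigError(f"site_jitter_sd must be >= 0, got {config.site_jitter_sd!r}")
    _count("n_genes_expression", config.n_genes_expression, minimum=1)
    if config.expr_noise_sd < 0:
        raise ConfigError(f"expr_noise_sd must be >= 0, got {config.expr_noise_sd!r}")
    if config.target_expr_corr is not None and not (
        -1.0 <= config.target_expr_corr <= 1.0
    ):
        raise ConfigError(
            f"target_expr_corr must lie in [-1, 1] or be None, got {config.target_expr_corr!r}"
        )
    _count("n_mutation_genes", config.n_mutation_genes)
    _count("n_cnv_genes", config.n_cnv_genes)
    lib = config.library_spec
    _count("library_spec.n_target_genes", lib.n_target_genes, minimum=1)
    _count("library_spec.guides_per_gene", lib.guides_per_gene, minimum=2)
    _count("library_spec.n_essential_genes", lib.n_essential_genes, minimum=1)
    _count("library_spec.essential_guides_per_gene", lib.essential_guides_per_gene, minimum=1)
    _count("library_spec.n_nontargeting_guides", lib.n_nontargeting_guides, minimum=1)
    _count("library_spec.n_nontargeting_genes", lib.n_nontargeting_genes, minimum=1)
    for key in (("pediatric", True), ("pediatric", False), ("adult", True), ("adult", False)):
        if key not in config.planted_beta:
            raise ConfigError(f"planted_beta missing entry for {key!r}")
    if config.background_effect_sd < 0:
        raise ConfigError("background_effect_sd must be >= 0")
    if config.guide_jitter_sd < 0:
        raise ConfigError("guide_jitter_sd must be >= 0")
    if config.sequencing_depth is not None:
        _positive("sequencing_depth", config.sequencing_depth)
    _positive("target_coverage", config.target_coverage)
    if config.dispersion < 0:
        raise ConfigError(f"dispersion must be >= 0, got {config.dispersion!r}")
    if config.plasmid_dispersion < 0:
        raise ConfigError(
            f"plasmid_dispersion must be >= 0, got {config.plasmid_dispersion!r}"
        )
    _count("n_screen_replicates", config.n_screen_replicates, minimum=1)
    grid = np.asarray(config.dose_grid, dtype=float)
    if grid.size < 6:
        raise ConfigError("dose_grid must contain at least 6 points")
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("dose_grid must be strictly increasing")
    if not math.isclose(float(grid.max()), 20.0, rel_tol=1e-9):
        raise ConfigError(f"dose_grid maximum must be 20 uM, got {grid.max()!r}")
    _count("n_dose_replicates", config.n_dose_replicates, minimum=1)
    _positive("hill", config.hill)
    if config.ic50_methylated_log10nM_sd < 0:
        raise ConfigError("ic50_methylated_log10nM_sd must be >= 0")
    max_dose_nM = float(grid.max()) * UM_TO_NM
    if config.resistant_ic50_floor_uM * UM_TO_NM <= max_dose_nM:
        raise ConfigError(
            "resistant_ic50_floor_uM must exceed the maximum dose "
            f"({grid.max()} uM), got {config.resistant_ic50_floor_uM!r}"
        )
    if config.viability_noise_sd < 0:
        raise ConfigError("viability_noise_sd must be >= 0")
    if not isinstance(config.seed, (int, np.integer)):
        raise ConfigError(f"seed must be an integer, got {config.seed!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated cohort."""

    methylation_state: pd.Series  # bool per sample
    true_ic50_nM: pd.Series  # float per sample
    gene_effects: pd.DataFrame  # gene x sample planted dependency effect
    cluster_membership: pd.Series  # bool per locus CpG
    exemplar_cpg: str


@dataclass
class CohortTables:
    """All generated data tables, sample identifiers consistent throughout."""

    annotations: pd.DataFrame  # sample_id-indexed: age, age_group, sex, cancer_type
    methylation: pd.DataFrame  # CpG x sample beta values
    methylation_annotation: pd.DataFrame  # cpg_id-indexed: locus, position, region
    expression: pd.DataFrame  # gene x sample
    mutations: pd.DataFrame  # gene x sample binary
    cnv: pd.DataFrame  # gene x sample binary
    library: pd.DataFrame  # guide_id-indexed: gene, role
    counts: pd.DataFrame  # guide x sequencing-sample integer counts
    count_samples: pd.DataFrame  # sample_id-indexed: cell_line, timepoint, replicate
    dose_response: pd.DataFrame  # long: cell_line, drug, dose_uM, replicate, viability


# ---------------------------------------------------------------------------
# individual generators


def generate_annotations(config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"PED{i + 1:03d}" for i in range(config.n_pediatric)] + [
        f"ADT{i + 1:03d}" for i in range(config.n_adult)
    ]
    ages = np.concatenate(
        [
            rng.integers(2, 19, size=config.n_pediatric),
            rng.integers(25, 71, size=config.n_adult),
        ]
    )
    groups = ["pediatric"] * config.n_pediatric + ["adult"] * config.n_adult
    sexes = rng.choice(["F", "M"], size=len(ids))
    cancer = ["pHGG"] * config.n_pediatric + ["aHGG"] * config.n_adult
    return pd.DataFrame(
        {"age": ages, "age_group": groups, "sex": sexes, "cancer_type": cancer},
        index=pd.Index(ids, name="sample_id"),
    )


def generate_states(
    config: TruthConfig, annotations: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    p = annotations["age_group"].map(
        {"pediatric": config.p_methylated_pediatric, "adult": config.p_methylated_adult}
    )
    states = rng.random(len(annotations)) < p.to_numpy()
    return pd.Series(states, index=annotations.index, name="methylated")


def generate_methylation(
    config: TruthConfig, states: pd.Series, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """CpG x sample beta matrix plus site annotation and cluster membership.

    Cluster sites share a per-sample latent level (high-beta distribution if
    the sample is methylated, low-beta otherwise) with independent site-level
    jitter; low sites are uniformly lowly methylated; remaining locus sites
    and background sites are independent of the latent state.
    """
    n = len(states)
    if n == 0:
        raise ConfigError("cohort size must be positive to generate methylation")
    k_cluster = config.cluster_size
    k_low = config.n_low_locus_cpgs
    k_other = config.n_locus_cpgs - k_cluster - k_low

    latent = np.where(
        states.to_numpy(),
        rng.beta(*config.beta_high_params, size=n),
        rng.beta(*config.beta_low_params, size=n),
    )
    cluster = np.clip(
        latent[None, :] + rng.normal(0.0, config.site_jitter_sd, size=(k_cluster, n)),
        0.0,
        1.0,
    )
    low = rng.beta(*config.low_site_beta_params, size=(k_low, n))
    other = rng.beta(0.8, 0.8, size=(k_other, n))
    background = rng.beta(0.8, 0.8, size=(config.n_background_cpgs, n))

    cluster_ids = [f"cg_cluster_{i + 1:02d}" for i in range(k_cluster)]
    low_ids = [f"cg_low_{i + 1:02d}" for i in range(k_low)]
    other_ids = [f"cg_locus_{i + 1:02d}" for i in range(k_other)]
    bg_ids = [f"cg_bg_{i + 1:04d}" for i in range(config.n_background_cpgs)]

    values = np.vstack([cluster, low, other, background]) if n else np.empty((0, 0))
    index = pd.Index(cluster_ids + low_ids + other_ids + bg_ids, name="cpg_id")
    meth = pd.DataFrame(values, index=index, columns=states.index)

    locus_ids = cluster_ids + low_ids + other_ids
    annotation = pd.DataFrame(
        {
            "locus": [LOCUS_GENE] * len(locus_ids) + ["background"] * len(bg_ids),
            "position": np.arange(len(index)) * 137 + 10_000,
            "region": (
                ["shore"] * len(cluster_ids)
                + ["island"] * len(low_ids)
                + ["other"] * len(other_ids)
                + ["other"] * len(bg_ids)
            ),
        },
        index=index,
    )
    membership = pd.Series(
        [True] * k_cluster + [False] * (len(locus_ids) - k_cluster),
        index=pd.Index(locus_ids, name="cpg_id"),
        name="cluster_member",
    )
    return meth, annotation, membership


def generate_expression(
    config: TruthConfig,
    methylation: pd.DataFrame,
    truth_membership: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gene x sample expression with one gene tied to cluster methylation.

    The locus gene's expression is ``intercept - slope * mean cluster beta``
    plus Gaussian noise. When ``target_expr_corr`` is set, the noise standard
    deviation is calibrated analytically from the realized methylation values
    so the Pearson correlation with the exemplar cluster CpG approximates the
    target; otherwise ``expr_noise_sd`` is used directly.
    """
    samples = methylation.columns
    n = len(samples)
    cluster_sites = truth_membership.index[truth_membership]
    slope = config.expr_methylation_slope

    if len(cluster_sites) > 0:
        m = methylation.loc[cluster_sites].mean(axis=0).to_numpy()
        exemplar = methylation.loc[cluster_sites[0]].to_numpy()
    else:
        m = np.zeros(n)
        exemplar = np.zeros(n)

    sigma = config.expr_noise_sd
    target = config.target_expr_corr
    if target is not None and len(cluster_sites) > 0 and n > 2:
        var_m = float(np.var(m))
        var_x = float(np.var(exemplar))
        cov = float(np.cov(m, exemplar, bias=True)[0, 1]) if var_x > 0 else 0.0
        r2 = min(target * target, 1.0 - 1e-12)
        if var_x > 0 and r2 > 0:
            sigma2 = slope * slope * (cov * cov / (r2 * var_x) - var_m)
            sigma = math.sqrt(max(sigma2, 0.0))
        else:
            sigma = config.expr_noise_sd

    focal = 10.0 - slope * m + rng.normal(0.0, sigma, size=n)
    others = rng.normal(5.0, 1.0, size=(config.n_genes_expression - 1, n))
    genes = [LOCUS_GENE] + [f"EXPR{i + 2:04d}" for i in range(config.n_genes_expression - 1)]
    values = np.vstack([focal[None, :], others])
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


def build_library(spec: LibrarySpec) -> pd.DataFrame:
    """Guide manifest: guide_id-indexed with gene and role columns."""
    rows: list[tuple[str, str, str]] = []
    target_genes = [FOCAL_GENE] + [f"TG{i + 2:04d}" for i in range(spec.n_target_genes - 1)]
    for gene in target_genes:
        for g in range(spec.guides_per_gene):
            rows.append((f"{gene}_sg{g + 1}", gene, "target"))
    for i in range(spec.n_essential_genes):
        gene = f"ESS{i + 1:03d}"
        for g in range(spec.essential_guides_per_gene):
            rows.append((f"{gene}_sg{g + 1}", gene, "essential_control"))
    per_gene = np.array_split(np.arange(spec.n_nontargeting_guides), spec.n_nontargeting_genes)
    for i, chunk in enumerate(per_gene):
        gene = f"NTC{i + 1}"
        for g, _ in enumerate(chunk):
            rows.append((f"{gene}_sg{g + 1}", gene, "nontargeting_control"))
    df = pd.DataFrame(rows, columns=["guide_id", "gene", "role"])
    return df.set_index("guide_id")


def generate_gene_effects(
    config: TruthConfig,
    annotations: pd.DataFrame,
    states: pd.Series,
    library: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Planted per-gene, per-sample dependency effects (log2 growth units).

    The focal gene carries the group x methylation-state effect; other target
    genes get a gene-level effect shared across samples; essential controls
    are fixed at -1 and nontargeting pseudo-genes at 0, matching the
    control-anchoring convention of the scoring stage.
    """
    genes = library["gene"].unique()
    roles = library.drop_duplicates("gene").set_index("gene")["role"]
    effects = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=states.index)
    focal_effects = [
        config.planted_beta[(annotations.loc[s, "age_group"], bool(states.loc[s]))]
        for s in states.index
    ]
    effects.loc[FOCAL_GENE] = focal_effects
    other_targets = [g for g in genes if roles[g] == "target" and g != FOCAL_GENE]
    per_gene = rng.normal(0.0, config.background_effect_sd, size=len(other_targets))
    for g, e in zip(other_targets, per_gene):
        effects.loc[g] = e
    essentials = [g for g in genes if roles[g] == "essential_control"]
    effects.loc[essentials] = -1.0
    return effects


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_screen_counts(
    config: TruthConfig,
    gene_effects: pd.DataFrame,
    library: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guide x sample counts: a day-0 plasmid reference plus endpoint replicates.

    Day-0 counts are overdispersed around uniform representation; endpoint
    expectation is the day-0 expectation times ``2**guide_effect`` where the
    guide effect is the planted gene effect plus guide-level jitter.
    """
    mu0 = config.reads_per_guide
    if mu0 < 1:
        logger.warning(
            "sequencing depth gives expected count %.3f < 1 per guide; "
            "library under-represented",
            mu0,
        )
    guides = library.index
    samples = gene_effects.columns
    jitter = rng.normal(0.0, config.guide_jitter_sd, size=len(guides))

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, int]] = []

    day0 = _nb_draw(rng, np.full(len(guides), mu0), config.plasmid_dispersion)
    columns["plasmid_day0"] = day0
    meta_rows.append(("plasmid_day0", "plasmid", "day0_reference", 1))

    gene_of_guide = library["gene"].to_numpy()
    gene_index = pd.Index(gene_effects.index)
    gene_pos = gene_index.get_indexer(gene_of_guide)
    effects = gene_effects.to_numpy()
    for j, sample in enumerate(samples):
        guide_effect = effects[gene_pos, j] + jitter
        mu21 = mu0 * np.power(2.0, guide_effect)
        for r in range(1, config.n_screen_replicates + 1):
            col = f"{sample}_d21_r{r}"
            columns[col] = _nb_draw(rng, mu21, config.dispersion)
            meta_rows.append((col, sample, "endpoint", r))

    counts = pd.DataFrame(columns, index=guides.rename("guide_id")).astype(np.int64)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "cell_line", "timepoint", "replicate"]
    ).set_index("sample_id")
    return counts, meta


def four_pl_viability(dose_nM, ic50_nM, top=1.0, bottom=0.0, hill=1.0):
    """Four-parameter logistic viability; dose 0 returns the top asymptote."""
    dose_nM = np.asarray(dose_nM, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose_nM > 0, (dose_nM / ic50_nM) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def generate_true_ic50(
    config: TruthConfig, states: pd.Series, rng: np.random.Generator
) -> pd.Series:
    """Per-sample true IC50 in nM: lognormal for methylated, censored floor otherwise."""
    n = len(states)
    methylated = 10 ** rng.normal(
        config.ic50_methylated_log10nM_mean,
        config.ic50_methylated_log10nM_sd,
        size=n,
    )
    floor_nM = config.resistant_ic50_floor_uM * UM_TO_NM
    resistant = floor_nM * 10 ** rng.uniform(0.0, 0.5, size=n)
    values = np.where(states.to_numpy(), methylated, resistant)
    return pd.Series(values, index=states.index, name="true_ic50_nM")


def generate_dose_response(
    config: TruthConfig, true_ic50_nM: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Long-format viability table for every (cell line, dose, replicate)."""
    doses = np.asarray(config.dose_grid, dtype=float)
    records = []
    for sample, ic50 in true_ic50_nM.items():
        clean = four_pl_viability(doses * UM_TO_NM, ic50, hill=config.hill)
        for r in range(1, config.n_dose_replicates + 1):
            noisy = clean + rng.normal(0.0, config.viability_noise_sd, size=len(doses))
            noisy = np.clip(noisy, 0.0, 1.2)
            for d, v in zip(doses, noisy):
                records.append((sample, DRUG_NAME, d, r, v))
    return pd.DataFrame(
        records, columns=["cell_line", "drug", "dose_uM", "replicate", "viability"]
    )


def generate_binary_block(
    prefix: str, n_genes: int, samples: pd.Index, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    values = (rng.random((n_genes, len(samples))) < rate).astype(np.int64)
    genes = pd.Index([f"{prefix}{i + 1:03d}" for i in range(n_genes)], name="gene")
    return pd.DataFrame(values, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# orchestration


def generate_cohort(config: TruthConfig) -> tuple[CohortTables, SyntheticTruth]:
    """Generate a full synthetic cohort and its planted ground truth.

    The draw order is fixed (annotations, states, methylation, expression,
    mutations, CNV, screen, dose-response) so that identical configurations
    produce byte-identical tables.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)

    annotations = generate_annotations(config, rng)
    states = generate_states(config, annotations, rng)
    methylation, meth_annotation, membership = generate_methylation(config, states, rng)
    expression = generate_expression(config, methylation, membership, rng)
    mutations = generate_binary_block(
        "MUT", config.n_mutation_genes, annotations.index, config.binary_event_rate, rng
    )
    cnv = generate_binary_block(
        "CNV", config.n_cnv_genes, annotations.index, config.binary_event_rate, rng
    )
    library = build_library(config.library_spec)
    gene_effects = generate_gene_effects(config, annotations, states, library, rng)
    counts, count_samples = generate_screen_counts(config, gene_effects, library, rng)
    true_ic50 = generate_true_ic50(config, states, rng)
    dose_response = generate_dose_response(config, true_ic50, rng)

    exemplar = membership.index[membership][0] if membership.any() else ""
    tables = CohortTables(
        annotations=annotations,
        methylation=methylation,
        methylation_annotation=meth_annotation,
        expression=expression,
        mutations=mutations,
        cnv=cnv,
        library=library,
        counts=counts,
        count_samples=count_samples,
        dose_response=dose_response,
    )
    truth = SyntheticTruth(
        methylation_state=states,
        true_ic50_nM=true_ic50,
        gene_effects=gene_effects,
        cluster_membership=membership,
        exemplar_cpg=exemplar,
    )
    return tables, truth


def config_from_dict(data: dict) -> TruthConfig:
    """Build a :class:`TruthConfig` from a plain (e.g. YAML-loaded) mapping."""
    data = dict(data)
    known = {f.name for f in fields(TruthConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown TruthConfig fields: {sorted(unknown)}")
    if "library_spec" in data and isinstance(data["library_spec"], dict):
        lib_known = {f.name for f in fields(LibrarySpec)}
        lib_unknown = set(data["library_spec"]) - lib_known
        if lib_unknown:
            raise ConfigError(f"unknown library_spec fields: {sorted(lib_unknown)}")
        data["library_spec"] = LibrarySpec(**data["library_spec"])
    if "planted_beta" in data and isinstance(data["planted_beta"], dict):
        parsed = {}
        for key, value in data["planted_beta"].items():
            if isinstance(key, str):
                group, state = key.rsplit("_", 1)
                parsed[(group, state.lower() in {"true", "methylated", "1"})] = float(value)
            else:
                parsed[tuple(key)] = float(value)
        data["planted_beta"] = parsed
    for name in ("beta_high_params", "beta_low_params", "low_site_beta_params", "dose_grid"):
        if name in data and data[name] is not None:
            data[name] = tuple(data[name])
    return TruthConfig(**data)
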