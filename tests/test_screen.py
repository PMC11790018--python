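"""Tests of CRISPR screen scoring, QC, and differential dependency."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methdep import screen
from methdep.stats import bh_adjust
from methdep.synthetic import generate_cohort

from conftest import small_config


def toy_library():
    rows = [
        ("A_sg1", "A", "target"),
        ("A_sg2", "A", "target"),
        ("B_sg1", "B", "target"),
        ("B_sg2", "B", "target"),
        ("ESS_sg1", "ESS", "essential_control"),
        ("ESS_sg2", "ESS", "essential_control"),
        ("NTC_sg1", "NTC", "nontargeting_control"),
        ("NTC_sg2", "NTC", "nontargeting_control"),
    ]
    return pd.DataFrame(rows, columns=["guide_id", "gene", "role"]).set_index("guide_id")


def toy_samples():
    return pd.DataFrame(
        {
            "cell_line": ["plasmid", "CL1"],
            "timepoint": ["day0_reference", "endpoint"],
            "replicate": [1, 1],
        },
        index=pd.Index(["ref", "end"], name="sample_id"),
    )


def norm_from_lfc(library, lfc: dict) -> pd.DataFrame:
    """Reference column of zeros; endpoint column equal to the wanted LFCs."""
    ref = pd.Series(0.0, index=library.index)
    end = pd.Series({g: float(lfc.get(g, 0.0)) for g in library.index})
    return pd.DataFrame({"ref": ref, "end": end})


class TestNormalizeCounts:
    def test_proportional_samples_normalize_identically(self):
        counts = pd.DataFrame({"a": [10, 30, 60], "b": [20, 60, 120]})
        norm = screen.normalize_counts(counts)
        assert np.allclose(norm["a"], norm["b"])

    def test_toy_counts_match_hand_computation(self):
        counts = pd.DataFrame({"s": [0, 99]})
        norm = screen.normalize_counts(counts, pseudocount=1, per_million=False)
        assert norm["s"].iloc[0] == pytest.approx(0.0)
        assert norm["s"].iloc[1] == pytest.approx(math.log2(100))

    def test_uniform_counts_normalize_uniformly(self):
        counts = pd.DataFrame({"a": [5, 5, 5], "b": [7, 7, 7]})
        norm = screen.normalize_counts(counts)
        assert norm["a"].nunique() == 1
        assert np.allclose(norm["a"], norm["b"])

    def test_zero_total_sample_raises_naming_sample(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            screen.normalize_counts(counts)


class TestBetaScores:
    def test_hand_computed_median_and_affine_anchor(self):
        """Gene with guide LFCs (-2, -1), nontargeting median 0, essential
        median -1 => beta = -1.5."""
        library = toy_library()
        norm = norm_from_lfc(
            library,
            {"A_sg1": -2.0, "A_sg2": -1.0, "ESS_sg1": -1.0, "ESS_sg2": -1.0},
        )
        betas = screen.compute_beta_scores(norm, toy_samples(), library)
        assert betas.scores.loc["A", "CL1"] == pytest.approx(-1.5)
        assert betas.scores.loc["B", "CL1"] == pytest.approx(0.0)
        assert betas.scores.loc["NTC", "CL1"] == pytest.approx(0.0)
        assert betas.scores.loc["ESS", "CL1"] == pytest.approx(-1.0)

    def test_null_endpoint_with_depleted_essentials_scores_targets_zero(self):
        library = toy_library()
        norm = norm_from_lfc(library, {"ESS_sg1": -1.0, "ESS_sg2": -1.0})
        betas = screen.compute_beta_scores(norm, toy_samples(), library)
        assert betas.scores.loc[["A", "B"], "CL1"].abs().max() == pytest.approx(0.0)

    def test_identical_control_medians_is_degenerate(self):
        library = toy_library()
        norm = norm_from_lfc(library, {})  # endpoint == reference everywhere
        with pytest.raises(ValueError, match="degenerate"):
            screen.compute_beta_scores(norm, toy_samples(), library)

    def test_control_medians_anchored_exactly(self, small_cohort):
        tables, _ = small_cohort
        norm = screen.normalize_counts(tables.counts)
        betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
        ess = betas.roles[betas.roles == "essential_control"].index
        ntc = betas.roles[betas.roles == "nontargeting_control"].index
        for cl in betas.scores.columns:
            assert betas.scores.loc[ntc, cl].median() == pytest.approx(0.0, abs=1e-9)
            assert betas.scores.loc[ess, cl].median() == pytest.approx(-1.0, abs=1e-9)

    def test_beta_invariant_to_per_sample_count_scaling(self, small_cohort):
        tables, _ = small_cohort
        norm_a = screen.normalize_counts(tables.counts)
        scaled = tables.counts.copy()
        endpoint_col = scaled.columns[1]
        scaled[endpoint_col] = scaled[endpoint_col] * 3
        norm_b = screen.normalize_counts(scaled)
        a = screen.compute_beta_scores(norm_a, tables.count_samples, tables.library)
        b = screen.compute_beta_scores(norm_b, tables.count_samples, tables.library)
        # pseudocount breaks exact invariance at low counts; tolerance reflects that
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=0.02)

    def test_recovers_planted_effects_on_small_cohorts(self):
        """Estimated beta correlates with planted gene effects and the
        planted pediatric-methylated focal effect (-0.92) is recovered."""
        rs, focal_means = [], []
        for seed in range(3):
            tables, truth = generate_cohort(small_config(seed=seed))
            norm = screen.normalize_counts(tables.counts)
            betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
            tg = betas.targets()
            planted = truth.gene_effects.loc[tg.index, tg.columns]
            rs.append(np.corrcoef(planted.to_numpy().ravel(), tg.to_numpy().ravel())[0, 1])
            groups = tables.annotations["age_group"]
            ped_meth = truth.methylation_state.index[
                (groups == "pediatric") & truth.methylation_state
            ]
            focal_means.append(tg.loc["MCL1", ped_meth].mean())
        assert np.mean(rs) >= 0.9
        assert abs(np.mean(focal_means) - (-0.92)) <= 0.15


class TestQC:
    def test_identical_replicates_pass_with_perfect_correlation(self):
        counts = pd.DataFrame({"r1": [10, 50, 200, 30], "r2": [10, 50, 200, 30]})
        samples = pd.DataFrame(
            {"cell_line": ["CL", "CL"], "timepoint": ["endpoint"] * 2, "replicate": [1, 2]},
            index=pd.Index(["r1", "r2"], name="sample_id"),
        )
        qc = screen.qc_screen(counts, samples)
        assert qc.replicate_correlations["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert qc.passed is True

    def test_shuffled_replicate_fails(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 1000, size=500)
        counts = pd.DataFrame({"r1": base, "r2": rng.permutation(base)})
        samples = pd.DataFrame(
            {"cell_line": ["CL", "CL"], "timepoint": ["endpoint"] * 2, "replicate": [1, 2]},
            index=pd.Index(["r1", "r2"], name="sample_id"),
        )
        qc = screen.qc_screen(counts, samples)
        assert abs(qc.replicate_correlations["pearson_r"].iloc[0]) < 0.3
        assert qc.passed is False

    def test_correlation_matches_closed_form_pearson(self):
        counts = pd.DataFrame({"r1": [10, 20, 40, 80], "r2": [12, 18, 50, 70]})
        samples = pd.DataFrame(
            {"cell_line": ["CL", "CL"], "timepoint": ["endpoint"] * 2, "replicate": [1, 2]},
            index=pd.Index(["r1", "r2"], name="sample_id"),
        )
        norm = screen.normalize_counts(counts)
        x, y = norm["r1"].to_numpy(), norm["r2"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        qc = screen.qc_screen(counts, samples)
        assert qc.replicate_correlations["pearson_r"].iloc[0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_single_replicate_reports_representation_only(self):
        counts = pd.DataFrame({"r1": [100, 5, 40]})
        samples = pd.DataFrame(
            {"cell_line": ["CL"], "timepoint": ["endpoint"], "replicate": [1]},
            index=pd.Index(["r1"], name="sample_id"),
        )
        qc = screen.qc_screen(counts, samples, floor=30)
        assert qc.passed is None
        assert qc.replicate_correlations.empty
        assert qc.representation.loc["r1", "fraction_represented"] == pytest.approx(2 / 3)


@pytest.mark.parametrize(
    "beta,expected",
    [(-0.92, True), (0.0, False), (-0.5, True), (-0.49, False)],
)
def test_hit_calls_inclusive_at_boundary(beta, expected):
    scores = pd.DataFrame({"CL": [beta]}, index=pd.Index(["G"], name="gene"))
    assert bool(screen.call_hits(scores).loc["G", "CL"]) is expected


class TestDifferentialDependency:
    @staticmethod
    def _frame(adult, pediatric, genes=("G1",)):
        cols = [f"A{i}" for i in range(len(adult))] + [f"P{i}" for i in range(len(pediatric))]
        data = np.array([list(adult) + list(pediatric)] * len(genes), dtype=float)
        scores = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=cols)
        groups = pd.Series(
            ["adult"] * len(adult) + ["pediatric"] * len(pediatric), index=cols
        )
        return scores, groups

    def test_matches_closed_form_pooled_t_oracle(self):
        adult, pediatric = (0.0, 0.1, -0.1), (-1.0, -0.9, -1.1)
        scores, groups = self._frame(adult, pediatric)
        row = screen.differential_dependency(scores, groups).loc["G1"]
        # independent pooled-variance oracle
        a, b = np.array(adult), np.array(pediatric)
        sp2 = ((a.var(ddof=1) * (len(a) - 1)) + (b.var(ddof=1) * (len(b) - 1))) / (
            len(a) + len(b) - 2
        )
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), len(a) + len(b) - 2)
        assert row["t_stat"] == pytest.approx(t, abs=1e-12)
        assert row["p_value"] == pytest.approx(p, abs=1e-12)
        assert row["delta"] == pytest.approx(1.0)
        assert row["call"] == "pediatric_specific"

    def test_planted_group_difference_calls_pediatric_specific(self):
        rng = np.random.default_rng(5)
        adult = -0.18 + rng.normal(0, 0.05, 8)
        pediatric = -0.92 + rng.normal(0, 0.05, 20)
        scores, groups = self._frame(adult, pediatric)
        row = screen.differential_dependency(scores, groups).loc["G1"]
        assert row["delta"] == pytest.approx(0.74, abs=0.1)
        assert row["call"] == "pediatric_specific"

    def test_identical_groups_call_none(self):
        scores, groups = self._frame((0.1, -0.1, 0.0), (0.1, -0.1, 0.0))
        row = screen.differential_dependency(scores, groups).loc["G1"]
        assert row["delta"] == pytest.approx(0.0)
        assert row["call"] == "none"

    def test_zero_variance_everywhere_flags_degenerate(self):
        scores, groups = self._frame((0.3, 0.3), (0.3, 0.3))
        row = screen.differential_dependency(scores, groups).loc["G1"]
        assert row["p_value"] == 1.0
        assert bool(row["degenerate"]) is True

    def test_fdr_never_below_p(self, small_cohort):
        tables, _ = small_cohort
        norm = screen.normalize_counts(tables.counts)
        betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
        diff = screen.differential_dependency(betas, tables.annotations["age_group"])
        assert (diff["fdr"] >= diff["p_value"] - 1e-12).all()

    def test_null_cohorts_control_false_discovery_rate(self):
        """Without a planted group difference, on average at most 5% of genes
        reach FDR < 0.05 (20 seeds)."""
        null_beta = {
            ("pediatric", True): -0.18,
            ("pediatric", False): -0.18,
            ("adult", True): -0.18,
            ("adult", False): -0.18,
        }
        rates = []
        for seed in range(20):
            tables, _ = generate_cohort(small_config(planted_beta=null_beta, seed=seed))
            norm = screen.normalize_counts(tables.counts)
            betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
            diff = screen.differential_dependency(betas, tables.annotations["age_group"])
            rates.append((diff["fdr"] < 0.05).mean())
        assert np.mean(rates) <= 0.05


def bh_step_up_oracle(pvalues):
    """Brute-force BH: adjusted_i = min_{j >= i in sorted order} p_(j) * m / j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for pos in range(m - 1, -1, -1):
        j = order[pos]
        running = min(running, p[j] * m / (pos + 1))
        adjusted[j] = running
    return adjusted


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20
    )
)
def test_bh_adjustment_matches_step_up_oracle(pvalues):
    assert np.allclose(bh_adjust(pvalues), bh_step_up_oracle(pvalues), atol=1e-12)


class TestPrevalence:
    def test_reference_prevalence_counts(self):
        hits = pd.Series(
            [True] * 49 + [False] * 16 + [True] * 1 + [False] * 9,
            index=[f"P{i}" for i in range(65)] + [f"A{i}" for i in range(10)],
        )
        groups = pd.Series(["pediatric"] * 65 + ["adult"] * 10, index=hits.index)
        res = screen.dependency_prevalence(hits, groups)
        assert res["percent"] == {"pediatric": 75, "adult": 10}
        assert res["counts"]["pediatric"] == (49, 65)
        assert res["p_value"] < 0.001

    def test_balanced_table_gives_p_one(self):
        hits = pd.Series([True, False, True, False], index=list("abcd"))
        groups = pd.Series(["pediatric", "pediatric", "adult", "adult"], index=hits.index)
        assert screen.dependency_prevalence(hits, groups)["p_value"] == pytest.approx(1.0)

    def test_three_zero_table_matches_enumeration(self):
        hits = pd.Series([True] * 3 + [False] * 3, index=list("abcdef"))
        groups = pd.Series(["pediatric"] * 3 + ["adult"] * 3, index=hits.index)
        assert screen.dependency_prevalence(hits, groups)["p_value"] == pytest.approx(0.1)

    def test_empty_group_raises(self):
        hits = pd.Series([True, False], index=["a", "b"])
        groups = pd.Series(["pediatric", "pediatric"], index=hits.index)
        with pytest.raises(ValueError, match="adult"):
            screen.dependency_prevalence(hits, groups)


class TestRankGenes:
    def test_sorted_betas_rank_ascending(self):
        scores = pd.DataFrame({"CL": [-2.0, -1.0, 0.0]}, index=pd.Index(["X", "Y", "Z"], name="gene"))
        ranks = screen.rank_genes(scores, "CL")
        assert list(ranks.index) == ["X", "Y", "Z"]
        assert list(ranks["rank"]) == [1, 2, 3]

    def test_ties_break_lexicographically(self):
        scores = pd.DataFrame({"CL": [0.0, 0.0, 0.0]}, index=pd.Index(["C", "A", "B"], name="gene"))
        assert list(screen.rank_genes(scores, "CL").index) == ["A", "B", "C"]

    def test_unknown_cell_line_raises(self):
        scores = pd.DataFrame({"CL": [0.0]}, index=pd.Index(["A"], name="gene"))
        with pytest.raises(ValueError, match="nope"):
            screen.rank_genes(scores, "nope")

    def test_planted_strongest_dependency_ranks_first(self):
        # modest background effects leave the focal -0.92 clearly strongest
        tables, truth = generate_cohort(small_config(background_effect_sd=0.15, seed=4))
        norm = screen.normalize_counts(tables.counts)
        betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
        groups = tables.annotations["age_group"]
        methylated_ped = truth.methylation_state.index[
            truth.methylation_state & (groups == "pediatric")
        ]
        top_hits = [screen.rank_genes(betas, cl).index[0] for cl in methylated_ped]
        assert top_hits.count("MCL1") / len(top_hits) >= 0.8
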