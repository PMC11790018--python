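"""End-to-end pipeline: simulate -> screen -> dose -> biomarker -> methylation -> report.

The pipeline is configured by a nested mapping (YAML on disk); defaults are
filled in, the resolved configuration is written verbatim into the output
directory, and a provenance record captures the package version, seeds and
parameters. All stage randomness flows from one global seed expanded per
stage, so a single integer reproduces the whole bundle.
"""
from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker, dose, methylation, screen, synthetic
from .exceptions import ConfigError, PipelineError
from .io import build_provenance, write_cohort, write_matrix, write_provenance

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "dose", "biomarker", "methylation", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},  # TruthConfig overrides
    "screen": {
        "hit_tau": screen.HIT_TAU,
        "delta_gate": screen.DELTA_GATE,
        "fdr_level": screen.FDR_LEVEL,
        "representation_floor": 30,
    },
    "dose": {
        "reference_cell_line": None,  # default: first adult line
        "sensitive_ic50_uM": dose.SENSITIVE_IC50_UM,
    },
    "biomarker": {
        "variable_k": biomarker.VARIABLE_K,
        "prefilter_k": biomarker.PREFILTER_K,
        "n_trees": 300,
        "cv_folds": 5,
        "importance_kind": "permutation",
        "top_score_threshold": biomarker.TOP_SCORE_THRESHOLD,
    },
    "methylation": {
        "locus": synthetic.LOCUS_GENE,
        "linkage": "average",
        "cut_height": methylation.CLUSTER_CUT_HEIGHT,
        "cutoff_grid": list(methylation.DEFAULT_CUTOFF_GRID),
        "age_cutoff": methylation.AGE_CUTOFF,
    },
}


def resolve_config(overrides: dict | None = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    overrides = overrides or {}
    unknown = set(overrides) - set(config)
    if unknown:
        raise ConfigError(f"unknown pipeline config sections: {sorted(unknown)}")
    for key, value in overrides.items():
        if isinstance(value, dict):
            section = config[key]
            bad = set(value) - set(section) if key != "simulate" else set()
            if bad:
                raise ConfigError(f"unknown option(s) in section {key!r}: {sorted(bad)}")
            section.update(value)
        else:
            config[key] = value
    bad_stages = set(config["stages"]) - set(STAGES)
    if bad_stages:
        raise ConfigError(f"unknown stage name(s): {sorted(bad_stages)}")
    return config


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return resolve_config(data)


def _stage_seed(global_seed: int, stage: str) -> int:
    # stable per-stage expansion of the global seed, kept below 2**31
    return int(np.random.SeedSequence([global_seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def run_pipeline(config: dict | None = None, outdir: Path | str = "methdep_run") -> dict:
    """Execute the enabled stages and write the report bundle.

    Returns the report dictionary. Each stage writes its tables under
    ``outdir/<stage>/``; the resolved config, provenance record and summary
    report land at the top level.
    """
    config = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    enabled = list(config["stages"])
    report: dict = {"stages_run": enabled}
    state: dict = {}

    for stage in [s for s in STAGES if s in enabled]:
        try:
            _STAGE_RUNNERS[stage](config, outdir, state, report)
        except (ConfigError,) as exc:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    provenance = build_provenance(parameters=config, seed=config["seed"])
    write_provenance(provenance, outdir / "provenance.json")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# stage runners


def _run_simulate(config, outdir, state, report):
    overrides = dict(config["simulate"])
    overrides.setdefault("seed", _stage_seed(config["seed"], "simulate"))
    truth_config = synthetic.config_from_dict(overrides)
    tables, truth = synthetic.generate_cohort(truth_config)
    write_cohort(tables, truth, outdir / "cohort")
    state["tables"] = tables
    state["truth"] = truth
    report["simulate"] = {
        "n_samples": int(len(tables.annotations)),
        "n_guides": int(len(tables.library)),
        "n_cpgs": int(len(tables.methylation)),
        "exemplar_cpg": truth.exemplar_cpg,
    }
    logger.info("[simulate] cohort of %d samples generated", len(tables.annotations))


def _require(state, key, stage):
    if key not in state:
        raise PipelineError(f"stage {stage!r} needs outputs of an earlier stage ({key})")
    return state[key]


def _run_screen(config, outdir, state, report):
    tables = _require(state, "tables", "screen")
    params = config["screen"]
    stage_dir = outdir / "screen"
    stage_dir.mkdir(parents=True, exist_ok=True)

    norm = screen.normalize_counts(tables.counts)
    qc = screen.qc_screen(
        tables.counts, tables.count_samples, floor=params["representation_floor"]
    )
    qc.replicate_correlations.to_csv(stage_dir / "qc_replicate_correlations.tsv", sep="\t", index=False)
    write_matrix(qc.representation, stage_dir / "qc_representation.tsv")

    betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
    write_matrix(betas.scores, stage_dir / "beta_scores.tsv")
    write_matrix(betas.anchoring, stage_dir / "anchoring.tsv")

    hits = screen.call_hits(betas, tau=params["hit_tau"])
    write_matrix(hits.astype(int), stage_dir / "hits.tsv")

    groups = tables.annotations["age_group"]
    diff = screen.differential_dependency(
        betas,
        groups,
        delta_gate=params["delta_gate"],
        fdr_level=params["fdr_level"],
    )
    write_matrix(diff, stage_dir / "differential_dependency.tsv")

    focal = synthetic.FOCAL_GENE
    prevalence = screen.dependency_prevalence(hits.loc[focal], groups)
    state["betas"] = betas
    state["hits"] = hits
    report["screen"] = {
        "qc_passed": qc.passed,
        "n_pediatric_specific": int((diff["call"] == "pediatric_specific").sum()),
        "n_adult_specific": int((diff["call"] == "adult_specific").sum()),
        "focal_gene": focal,
        "focal_delta": float(diff.loc[focal, "delta"]),
        "focal_fdr": float(diff.loc[focal, "fdr"]),
        "focal_prevalence_percent": prevalence["percent"],
        "focal_prevalence_p": prevalence["p_value"],
    }
    logger.info("[screen] %d pediatric-specific genes", report["screen"]["n_pediatric_specific"])


def _run_dose(config, outdir, state, report):
    tables = _require(state, "tables", "dose")
    params = config["dose"]
    stage_dir = outdir / "dose"
    stage_dir.mkdir(parents=True, exist_ok=True)

    reference = params["reference_cell_line"]
    if reference is None:
        adults = tables.annotations.index[tables.annotations["age_group"] == "adult"]
        reference = adults[0] if len(adults) > 0 else tables.annotations.index[0]
    fits = dose.fit_cohort(
        tables.dose_response,
        reference_cell_line=reference,
        ic50_threshold_uM=params["sensitive_ic50_uM"],
    )
    fits.to_csv(stage_dir / "fits.tsv", sep="\t")
    state["fits"] = fits
    per_line = fits.reset_index().set_index("cell_line")
    state["auc"] = per_line["auc_raw"]
    state["labels"] = per_line["label"]
    n_sens = int((per_line["label"] == "sensitive").sum())
    report["dose"] = {
        "reference_cell_line": reference,
        "n_assays": int(len(fits)),
        "n_sensitive": n_sens,
        "fraction_sensitive": n_sens / len(fits) if len(fits) else float("nan"),
    }
    logger.info("[dose] %d / %d assays sensitive", n_sens, len(fits))


def _run_biomarker(config, outdir, state, report):
    tables = _require(state, "tables", "biomarker")
    auc = _require(state, "auc", "biomarker")
    params = config["biomarker"]
    stage_dir = outdir / "biomarker"
    stage_dir.mkdir(parents=True, exist_ok=True)

    clinical = tables.annotations[["cancer_type", "sex", "age_group"]]
    features = biomarker.assemble_feature_table(
        tables.expression,
        tables.methylation,
        tables.mutations,
        tables.cnv,
        clinical,
        variable_k=params["variable_k"],
    )
    selected = biomarker.prefilter_top_correlated(features, auc, k=params["prefilter_k"])
    model = biomarker.RandomForestBiomarker(
        n_trees=params["n_trees"],
        cv_folds=params["cv_folds"],
        importance_kind=params["importance_kind"],
        random_state=_stage_seed(config["seed"], "biomarker"),
    ).fit(selected.values, auc)
    importance = biomarker.normalize_importance(
        model.feature_importances_, threshold=params["top_score_threshold"]
    )
    write_matrix(importance.table, stage_dir / "importance_report.tsv")
    correlates = biomarker.single_correlate(selected, auc)
    write_matrix(correlates.sort_values("rank"), stage_dir / "single_correlates.tsv")
    with open(stage_dir / "performance.json", "w") as fh:
        json.dump(
            {
                "performance": model.performance_,
                "model_gradient": importance.model_gradient,
                "model_concentration": importance.model_concentration,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    state["importance"] = importance
    report["biomarker"] = {
        "n_features_assembled": int(features.values.shape[1]),
        "n_features_model": int(selected.values.shape[1]),
        "oof_spearman": model.performance_.get("spearman"),
        "top_features": importance.top_features[:20],
    }
    logger.info("[biomarker] top features: %s", importance.top_features[:5])


def _run_methylation(config, outdir, state, report):
    tables = _require(state, "tables", "methylation")
    params = config["methylation"]
    stage_dir = outdir / "methylation"
    stage_dir.mkdir(parents=True, exist_ok=True)

    sub = methylation.locus_submatrix(
        tables.methylation, tables.methylation_annotation, params["locus"]
    )
    assignment = methylation.cluster_cpg_sites(
        sub, linkage=params["linkage"], cut_height=params["cut_height"]
    )
    assignment.labels.to_frame().to_csv(stage_dir / "cluster_assignment.tsv", sep="\t")

    result: dict = {
        "locus": params["locus"],
        "n_locus_cpgs": int(len(sub)),
        "n_clusters": int(assignment.cluster_means.size),
        "n_low_methylation_clusters": int(assignment.low_methylation.sum()),
    }

    if "auc" in state:
        waterfall = methylation.correlate_sites_with_response(sub, state["auc"])
        write_matrix(waterfall, stage_dir / "waterfall.tsv")
        result["top_waterfall_cpg"] = str(waterfall.index[0])
        result["top_waterfall_r"] = float(waterfall["pearson_r"].iloc[0])
    if "labels" in state:
        # scan on the strongest-candidate cluster's exemplar site
        candidates = assignment.candidate_sites
        exemplar = None
        if candidates and "auc" in state:
            exemplar = (
                waterfall.loc[waterfall.index.intersection(candidates)]
                .sort_values(["pearson_r", "rank"])  # most negative first
                .index[0]
            )
        elif candidates:
            exemplar = candidates[0]
        if exemplar is not None:
            scan = methylation.scan_threshold(
                sub.loc[exemplar],
                state["labels"],
                candidates=params["cutoff_grid"],
            )
            scan.table.to_csv(stage_dir / "threshold_scan.tsv", sep="\t")
            result["scan_cpg"] = str(exemplar)
            result["chosen_cutoff"] = float(scan.chosen_cutoff)

    ages = tables.annotations["age"]
    cluster_label = assignment.labels.value_counts().idxmax()
    summary = methylation.summarize_age_methylation(
        tables.methylation,
        assignment.members(int(cluster_label)),
        ages,
        age_cutoff=params["age_cutoff"],
    )
    with open(stage_dir / "age_group_comparison.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "summary"}, fh, indent=2)
        fh.write("\n")
    result["age_comparison_p"] = summary["p_value"]
    report["methylation"] = result
    logger.info("[methylation] chosen cutoff: %s", result.get("chosen_cutoff"))


def _run_report(config, outdir, state, report):
    # The summary report is assembled incrementally by each stage; here we
    # only distill the headline biomarker nomination.
    nomination = {}
    importance = state.get("importance")
    if importance is not None:
        meth_top = [f for f in importance.top_features if f.startswith("methylation:")]
        nomination["top_methylation_features"] = meth_top
    if "methylation" in report:
        nomination["threshold_biomarker"] = report["methylation"].get("scan_cpg")
        nomination["chosen_cutoff"] = report["methylation"].get("chosen_cutoff")
    report["nomination"] = nomination


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "screen": _run_screen,
    "dose": _run_dose,
    "biomarker": _run_biomarker,
    "methylation": _run_methylation,
    "report": _run_report,
}
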