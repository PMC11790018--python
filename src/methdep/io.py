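"""Table I/O with schema validation, plus provenance records.

All interchange is plain TSV/CSV with documented headers; matrices are
written with their feature identifier as the index column. Readers check
column names, dtypes and value ranges, and raise :class:`SchemaError`
naming the file, column and first offending row.
"""
from __future__ import annotations

import hashlib
import json
import platform
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .synthetic import CohortTables, SyntheticTruth


def _package_version() -> str:
    try:
        return pkg_version("methdep")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


# ---------------------------------------------------------------------------
# generic helpers


def write_matrix(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t")


def _read_tsv(path: Path | str, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    return pd.read_csv(path, sep="\t", index_col=index_col)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _first_offender(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


# ---------------------------------------------------------------------------
# table readers


def read_methylation_matrix(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicate CpG id {df.index[df.index.duplicated()][0]!r}")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values > 1)
        if bad.any():
            i = _first_offender(bad)
            raise SchemaError(
                f"{path}: column {col!r} row {df.index[i]!r}: "
                f"value {df[col].iloc[i]!r} outside [0, 1]"
            )
    return df.astype(float)


def read_expression_matrix(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            i = _first_offender(values.isna())
            raise SchemaError(
                f"{path}: column {col!r} row {df.index[i]!r}: non-numeric value"
            )
    return df.astype(float)


def read_binary_matrix(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = ~values.isin([0, 1])
        if bad.any():
            i = _first_offender(bad)
            raise SchemaError(
                f"{path}: column {col!r} row {df.index[i]!r}: "
                f"value {df[col].iloc[i]!r} is not 0/1"
            )
    return df.astype(np.int64)


def read_library(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["gene", "role"], path)
    valid = {"target", "essential_control", "nontargeting_control"}
    bad = ~df["role"].isin(valid)
    if bad.any():
        i = _first_offender(bad)
        raise SchemaError(
            f"{path}: column 'role' row {df.index[i]!r}: "
            f"invalid role {df['role'].iloc[i]!r}"
        )
    return df


def read_count_matrix(path: Path | str, library: pd.DataFrame | None = None) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values != np.floor(values.fillna(0)))
        if bad.any():
            i = _first_offender(bad)
            raise SchemaError(
                f"{path}: column {col!r} row {df.index[i]!r}: "
                f"value {df[col].iloc[i]!r} is not a nonnegative integer"
            )
    df = df.astype(np.int64)
    if library is not None:
        unknown = df.index.difference(library.index)
        if len(unknown) > 0:
            raise SchemaError(f"{path}: guide {unknown[0]!r} absent from the library manifest")
        missing = library.index.difference(df.index)
        if len(missing) > 0:
            raise SchemaError(f"{path}: library guide {missing[0]!r} missing from counts")
    return df


def read_count_samples(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["cell_line", "timepoint", "replicate"], path)
    valid = {"day0_reference", "endpoint"}
    bad = ~df["timepoint"].isin(valid)
    if bad.any():
        i = _first_offender(bad)
        raise SchemaError(
            f"{path}: column 'timepoint' row {df.index[i]!r}: "
            f"invalid timepoint {df['timepoint'].iloc[i]!r}"
        )
    return df


def read_annotations(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["age", "age_group", "sex", "cancer_type"], path)
    return df


def read_groups(path: Path | str) -> pd.Series:
    df = _read_tsv(path)
    _require_columns(df, ["group"], path)
    return df["group"]


def read_dose_response(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    df = pd.read_csv(path)
    _require_columns(df, ["cell_line", "drug", "dose_uM", "replicate", "viability"], path)
    v = pd.to_numeric(df["viability"], errors="coerce")
    bad = v.isna() | (v < 0) | ~np.isfinite(v)
    if bad.any():
        i = _first_offender(bad)
        raise SchemaError(
            f"{path}: column 'viability' row {i}: "
            f"value {df['viability'].iloc[i]!r} is not a finite nonnegative number"
        )
    d = pd.to_numeric(df["dose_uM"], errors="coerce")
    if (d.isna() | (d < 0)).any():
        i = _first_offender(d.isna() | (d < 0))
        raise SchemaError(f"{path}: column 'dose_uM' row {i}: invalid dose")
    return df


def read_truth_tables(directory: Path | str) -> SyntheticTruth:
    directory = Path(directory)
    states = _read_tsv(directory / "truth_states.tsv")
    membership = _read_tsv(directory / "truth_cluster_membership.tsv")
    effects = _read_tsv(directory / "truth_gene_effects.tsv")
    return SyntheticTruth(
        methylation_state=states["methylated"].astype(bool),
        true_ic50_nM=states["true_ic50_nM"].astype(float),
        gene_effects=effects.astype(float),
        cluster_membership=membership["cluster_member"].astype(bool),
        exemplar_cpg=str(
            membership.index[membership["cluster_member"].astype(bool)][0]
        )
        if membership["cluster_member"].astype(bool).any()
        else "",
    )


# ---------------------------------------------------------------------------
# cohort bundle


COHORT_FILES = {
    "annotations": "annotations.tsv",
    "methylation": "methylation.tsv",
    "methylation_annotation": "methylation_annotation.tsv",
    "expression": "expression.tsv",
    "mutations": "mutations.tsv",
    "cnv": "cnv.tsv",
    "library": "library.tsv",
    "counts": "counts.tsv",
    "count_samples": "count_samples.tsv",
}


def write_cohort(tables: CohortTables, truth: SyntheticTruth | None, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, filename in COHORT_FILES.items():
        write_matrix(getattr(tables, attr), outdir / filename)
    tables.dose_response.to_csv(outdir / "dose_response.csv", index=False)
    if truth is not None:
        states = pd.DataFrame(
            {
                "methylated": truth.methylation_state,
                "true_ic50_nM": truth.true_ic50_nM,
            }
        )
        write_matrix(states, outdir / "truth_states.tsv")
        write_matrix(
            truth.cluster_membership.to_frame(), outdir / "truth_cluster_membership.tsv"
        )
        write_matrix(truth.gene_effects, outdir / "truth_gene_effects.tsv")


def read_cohort(directory: Path | str) -> CohortTables:
    directory = Path(directory)
    library = read_library(directory / "library.tsv")
    return CohortTables(
        annotations=read_annotations(directory / "annotations.tsv"),
        methylation=read_methylation_matrix(directory / "methylation.tsv"),
        methylation_annotation=_read_tsv(directory / "methylation_annotation.tsv"),
        expression=read_expression_matrix(directory / "expression.tsv"),
        mutations=read_binary_matrix(directory / "mutations.tsv"),
        cnv=read_binary_matrix(directory / "cnv.tsv"),
        library=library,
        counts=read_count_matrix(directory / "counts.tsv", library=library),
        count_samples=read_count_samples(directory / "count_samples.tsv"),
        dose_response=read_dose_response(directory / "dose_response.csv"),
    )


# ---------------------------------------------------------------------------
# provenance


def file_checksum(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_provenance(parameters: dict, seed: int, inputs: dict[str, str] | None = None) -> dict:
    record = {
        "package": "methdep",
        "version": _package_version(),
        "python": platform.python_version(),
        "seed": seed,
        "parameters": parameters,
    }
    if inputs:
        record["inputs"] = {
            name: {"path": str(p), "sha256": file_checksum(p)} for name, p in inputs.items()
        }
    return record


def write_provenance(record: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
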