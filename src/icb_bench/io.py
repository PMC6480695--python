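"""TSV readers/writers and run configuration.

All tables are tab-separated text with ``NA`` for missing values:

* expression — first column ``gene``, one column per patient, TPM values;
* mutations — minimal MAF-like dialect: patient_id, hugo_symbol,
  chromosome, position (1-based), ref, alt, variant_class;
* clinical — patient_id, response_category, os_value, os_unit, os_known;
* scores / calls — patient_id plus one column per marker.

Every writer's output is re-readable by the matching reader, bit-identically
for numeric content.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError, SchemaError

__all__ = [
    "read_expression", "write_expression",
    "read_mutations", "write_mutations",
    "read_clinical", "write_clinical",
    "read_scores", "write_scores",
    "read_labels", "write_labels",
    "read_response_mapping", "map_response_categories",
    "read_cohort",
    "RunConfig", "load_run_config",
]

NA = "NA"

MUTATION_COLUMNS = [
    "patient_id", "hugo_symbol", "chromosome", "position", "ref", "alt", "variant_class",
]
CLINICAL_COLUMNS = ["patient_id", "response_category", "os_value", "os_unit", "os_known"]


def _check_header(path: Path, first_column: str) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"), None)
    if not header or header[0] != first_column:
        raise SchemaError(f"{path}: expected first column {first_column!r}, got {header!r}")
    return header


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x patients TPM matrix.

    Duplicate gene rows are collapsed by the per-patient maximum (with a
    warning); duplicate patient columns and non-numeric cells are errors,
    the latter reported with row/column coordinates.
    """
    path = Path(path)
    header = _check_header(path, "gene")
    patients = header[1:]
    dup_cols = sorted({p for p in patients if patients.count(p) > 1})
    if dup_cols:
        raise SchemaError(f"{path}: duplicate patient columns {dup_cols}")
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, na_values=[NA], keep_default_na=False)
    try:
        values = raw.astype(float)
    except ValueError:
        for i, (gene, row) in enumerate(raw.iterrows()):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at gene {gene!r} "
                        f"(data row {i + 1}), column {raw.columns[j]!r}"
                    ) from None
        raise
    values.index = values.index.str.strip()
    if values.index.duplicated().any():
        dups = sorted(set(values.index[values.index.duplicated()]))
        warnings.warn(f"{path}: duplicate gene rows collapsed by max: {dups}", stacklevel=2)
        values = values.groupby(level=0, sort=False).max()
    values.index.name = "gene"
    return values


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", na_rep=NA)


def read_mutations(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, na_values=[NA], keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mutation columns {missing}")
    return frame[MUTATION_COLUMNS]


def write_mutations(records: pd.DataFrame, path: str | Path) -> None:
    records[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_clinical(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing clinical columns {missing}")
    frame["os_known"] = frame["os_known"].map(
        {True: True, False: False, "True": True, "False": False}
    )
    if frame["os_known"].isna().any():
        raise ParseError(f"{path}: os_known must be True/False")
    frame["os_value"] = frame["os_value"].astype(float)
    return frame[CLINICAL_COLUMNS]


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_scores(path: str | Path) -> pd.DataFrame:
    """patient_id-indexed table of per-marker scores or binary calls.

    Numeric columns come back as float; annotation columns (e.g. ``label``,
    ``cohort`` on a merged table) keep their strings.
    """
    _check_header(Path(path), "patient_id")
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    for column in frame.columns:
        try:
            frame[column] = frame[column].astype(float)
        except (TypeError, ValueError):
            pass
    return frame


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="patient_id", na_rep=NA)


def read_labels(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if "patient_id" not in frame.columns or "label" not in frame.columns:
        raise SchemaError(f"{path}: labels need patient_id and label columns")
    return frame


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_response_mapping(path: str | Path) -> dict[str, str]:
    """Flat key-value text mapping study response strings to canonical codes.

    One ``original<TAB>code`` (or ``original = code``) pair per line; blank
    lines and ``#`` comments ignored.
    """
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            key, _, value = line.partition("\t")
        elif "=" in line:
            key, _, value = line.partition("=")
        else:
            raise ParseError(f"{path}:{lineno}: expected 'original<TAB>code' or 'original = code'")
        mapping[key.strip()] = value.strip()
    return mapping


def map_response_categories(clinical: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Translate study-specific response strings to the canonical six codes."""
    out = clinical.copy()
    out["response_category"] = out["response_category"].map(
        lambda v: mapping.get(v, v)
    )
    return out


def read_cohort(directory: str | Path, cohort_id: str):
    """Re-assemble a :class:`~icb_bench.simulate.CohortBundle` from TSV files."""
    from .simulate import CohortBundle

    directory = Path(directory)
    clinical = read_clinical(directory / f"{cohort_id}_clinical.tsv")
    expr_path = directory / f"{cohort_id}_expression.tsv"
    mut_path = directory / f"{cohort_id}_mutations.tsv"
    plug_path = directory / f"{cohort_id}_plugin_scores.tsv"
    expression = read_expression(expr_path) if expr_path.exists() else None
    mutations = read_mutations(mut_path) if mut_path.exists() else None
    plugin_scores = read_scores(plug_path) if plug_path.exists() else None
    return CohortBundle(
        cohort_id=cohort_id,
        clinical=clinical,
        expression=expression,
        mutations=mutations,
        plugin_scores=plugin_scores,
        rna_available=expression is not None,
        dna_available=mutations is not None,
    )


@dataclass
class RunConfig:
    """Constants and paths steering one full pipeline run.

    When ``cohort_dir`` is unset the run simulates its cohorts from the
    default five-study configuration using ``seed``.
    """

    out_dir: Path = Path("results/run")
    seed: int = 0
    cohort_dir: Path | None = None
    cohort_ids: list[str] = field(default_factory=list)
    response_mapping: Path | None = None
    expression_unit: str = "TPM"  # TPM or FPKM, accepted interchangeably
    os_cutoff_years: float = 2.0
    r_cut: float = 0.5
    alpha: float = 0.01
    auc_floor: float = 0.65
    test_fraction: float = 0.2
    iterations: int = 10_000
    include_mutational_load: bool = True
    tie_to_responder: bool = True
    dedup_mutations: bool = False

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if not 0.0 < self.r_cut < 1.0 or not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("r_cut and alpha must be in (0, 1)")
        if self.expression_unit not in ("TPM", "FPKM"):
            raise ConfigurationError(f"unknown expression unit {self.expression_unit!r}")
        if self.os_cutoff_years <= 0 or self.auc_floor < 0:
            raise ConfigurationError("os_cutoff_years must be > 0 and auc_floor >= 0")
        if self.cohort_dir is not None:
            if not Path(self.cohort_dir).is_dir():
                raise ConfigurationError(f"cohort_dir {self.cohort_dir} does not exist")
            if not self.cohort_ids:
                raise ConfigurationError("cohort_ids required when cohort_dir is set")
        if self.response_mapping is not None and not Path(self.response_mapping).is_file():
            raise ConfigurationError(f"response mapping {self.response_mapping} does not exist")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML) run configuration file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected flat key-value mappings")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown configuration keys {sorted(unknown)}")
    for key in ("out_dir", "cohort_dir", "response_mapping"):
        if key in data and data[key] is not None:
            data[key] = Path(data[key])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
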