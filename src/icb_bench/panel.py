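"""Built-in biomarker panel and continuous per-patient marker scoring.

The panel collects 18 published predictors of response to immune-checkpoint
inhibitors: single immune genes (PD-L1/CD274, PD-1/PDCD1, CTLA4, the POLE
family, AXL, PDCD1LG2), interferon-gamma and ICB-resistance expression
signatures, tumor mutational load from whole-exome sequencing, and two
external algorithmic scores (TIDE, ImmunoPhenoScore) accepted as plug-in
columns rather than recomputed.

Expression markers are scored on log2(TPM + 1); a gene-set signature is the
arithmetic mean of its member genes' log values (the minimal convention for
score-level signatures — the aggregation rule is recorded in output
metadata). Mutational load is the raw variant-record count per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IdentifierMismatchError, MissingGeneError, MissingSignatureError

__all__ = [
    "MarkerDefinition",
    "MarkerScoreTable",
    "builtin_panel",
    "panel_by_name",
    "score_single_gene",
    "score_gene_set",
    "score_mutational_load",
    "assemble_scores",
    "GENE_SET_AGGREGATION",
    "IPS_REFERENCE_GENES",
]

#: Aggregation rule used for every gene-set signature, recorded in run manifests.
GENE_SET_AGGREGATION = "mean of log2(TPM+1) over member genes found in the matrix"

ORIGIN_RNA = "RNA"
ORIGIN_DNA = "DNA"

KIND_SINGLE = "single-gene"
KIND_GENE_SET = "gene-set"
KIND_COUNT = "count"
KIND_PLUGIN = "plug-in"


@dataclass(frozen=True)
class MarkerDefinition:
    """A named biomarker with its data origin, scoring kind and gene list."""

    name: str
    origin: str
    kind: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.origin not in (ORIGIN_RNA, ORIGIN_DNA):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.kind == KIND_SINGLE and len(self.genes) != 1:
            raise ValueError(f"{self.name}: single-gene marker needs exactly 1 gene")
        if self.kind == KIND_GENE_SET and len(self.genes) < 2:
            raise ValueError(f"{self.name}: gene-set marker needs >= 2 genes")
        if self.kind in (KIND_COUNT, KIND_PLUGIN) and self.genes:
            raise ValueError(f"{self.name}: {self.kind} marker carries no gene list")


IFNG_REDUCED = ("CXCL10", "CXCL9", "HLA-DRA", "IDO1", "IFNG", "STAT1")

IFNG_EXPANDED = (
    "CCL5", "CD2", "CD3D", "CD3E", "CIITA", "CXCL10", "CXCL13", "CXCR6",
    "GZMB", "GZMK", "HLA-DRA", "HLA-E", "IDO1", "IL2RG", "LAG3", "NKG7",
    "STAT1", "TAGAP",
)

ICB_RESIST_1 = (
    "ADAMTS7", "AXL", "COL12A1", "COL8A1", "FAP", "FBLN1", "INHBA", "LOXL2",
    "MMP1", "MMP13", "ROR2", "TAGLN", "TWIST2", "WNT5A",
)

ICB_RESIST_2 = ("CNN1", "COL3A1", "MXRA7", "SERPINF2")

ICB_RESIST_3 = ("CST2", "LAMA3")

AXL_PATHWAY = (
    "AXL", "FLT1", "FLT4", "GAS6", "KDR", "MERTK", "MET", "RET", "TEK", "TYRO3",
)

# Member genes of the ImmunoPhenoScore model, kept for reference only: IPS is a
# plug-in marker and is never recomputed from expression here.
IPS_REFERENCE_GENES = (
    "ACAP1", "ADRM1", "AHSA1", "AIM2", "APOL3", "ARHGAP10", "ATM", "ATP10D",
    "B2M", "BIRC3", "BRIP1", "C1GALT1C1", "C3AR1", "CASP3", "CASQ1", "CCL20",
    "CCL3L1", "CCL4", "CCL5", "CCNB1", "CCR2", "CCR5", "CCR7", "CCT6B", "CD14",
    "CD160", "CD2", "CD27", "CD274", "CD300E", "CD37", "CD3D", "CD3E", "CD3G",
    "CD55", "CD69", "CD72", "CD86", "CD8A", "CETN3", "CFLAR", "CLEC5A",
    "CMKLR1", "CSE1L", "CTLA4", "CXCR4", "DAPP1", "DARS", "DOCK9", "DUSP2",
    "ESCO2", "ETS1", "EXO1", "EXOC6", "EXOSC9", "EZH2", "FCGR2A", "FCGR2B",
    "FCGR3A", "FCRL6", "FERMT3", "FLT3LG", "FOXP3", "GDE1", "GEMIN6", "GNLY",
    "GPSM3", "GPT2", "GZMA", "GZMH", "GZMK", "GZMM", "HAPLN3", "HAVCR2",
    "HLA-A", "HLA-B", "HLA-C", "HLA-DMB", "HLA-DPA1", "HLA-DPB1", "HLA-E",
    "HLA-F", "IARS", "ICOS", "IDO1", "IFI16", "IL18BP", "IL2RB", "IL34",
    "IL4R", "ITGA4", "ITGAL", "ITGAM", "KIF11", "KNTC1", "L1CAM", "LAG3",
    "LCK", "LIME1", "LIPA", "LRP1", "LRRC42", "LTK", "MARCO", "MMP12", "MNDA",
    "MPZL1", "MRC1", "MS4A6A", "NCOA4", "NEFL", "NFKBIA", "NKG7", "NUF2",
    "PARVG", "PDCD1", "PDCD1LG2", "PDGFRL", "PELO", "PIK3IP1", "PLEK", "PRC1",
    "PRSS23", "PSAP", "PSAT1", "PTGER2", "PTGES2", "PTGIR", "PTGS1", "PTRH2",
    "REPS1", "RGS1", "RTKN2", "S100A8", "S100A9", "SAMSN1", "SCG2", "SDPR",
    "SELL", "SETD7", "SIGLEC14", "SIGLEC6", "SIK1", "ST8SIA4", "STAB1", "TAL1",
    "TAP1", "TAP2", "TFEC", "TIGIT", "TIMM13", "TIPIN", "TPK1", "TRAT1",
    "TRIB2", "UQCRB", "USP9Y", "WIPF1", "ZAP70", "ZCRB1",
)

_PANEL: tuple[MarkerDefinition, ...] = (
    MarkerDefinition("CD274", ORIGIN_RNA, KIND_SINGLE, ("CD274",)),
    MarkerDefinition("Mutational load", ORIGIN_DNA, KIND_COUNT),
    MarkerDefinition("IFN-y (reduced set)", ORIGIN_RNA, KIND_GENE_SET, IFNG_REDUCED),
    MarkerDefinition("IFN-y (expanded set)", ORIGIN_RNA, KIND_GENE_SET, IFNG_EXPANDED),
    MarkerDefinition("IPS", ORIGIN_RNA, KIND_PLUGIN),
    MarkerDefinition("PDCD1", ORIGIN_RNA, KIND_SINGLE, ("PDCD1",)),
    MarkerDefinition("POLE", ORIGIN_RNA, KIND_SINGLE, ("POLE",)),
    MarkerDefinition("POLE2", ORIGIN_RNA, KIND_SINGLE, ("POLE2",)),
    MarkerDefinition("POLE3", ORIGIN_RNA, KIND_SINGLE, ("POLE3",)),
    MarkerDefinition("POLE4", ORIGIN_RNA, KIND_SINGLE, ("POLE4",)),
    MarkerDefinition("CTLA4", ORIGIN_RNA, KIND_SINGLE, ("CTLA4",)),
    MarkerDefinition("PDCD1LG2", ORIGIN_RNA, KIND_SINGLE, ("PDCD1LG2",)),
    MarkerDefinition("ICB resist. signature 1", ORIGIN_RNA, KIND_GENE_SET, ICB_RESIST_1),
    MarkerDefinition("ICB resist. signature 2", ORIGIN_RNA, KIND_GENE_SET, ICB_RESIST_2),
    MarkerDefinition("ICB resist. signature 3", ORIGIN_RNA, KIND_GENE_SET, ICB_RESIST_3),
    MarkerDefinition("AXL pathway", ORIGIN_RNA, KIND_GENE_SET, AXL_PATHWAY),
    MarkerDefinition("AXL", ORIGIN_RNA, KIND_SINGLE, ("AXL",)),
    MarkerDefinition("TIDE", ORIGIN_RNA, KIND_PLUGIN),
)


def builtin_panel() -> list[MarkerDefinition]:
    """Return the 18 built-in marker definitions, in canonical panel order."""
    return list(_PANEL)


def panel_by_name(panel: Sequence[MarkerDefinition] | None = None) -> dict[str, MarkerDefinition]:
    """Index a panel (default: built-in) by marker name."""
    return {m.name: m for m in (panel if panel is not None else _PANEL)}


@dataclass
class MarkerScoreTable:
    """Patients x markers continuous scores; missing scores are NaN."""

    scores: pd.DataFrame  # index: patient_id, columns: marker names
    missing_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.scores.columns)


def _log_tpm(values: pd.Series | np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def score_single_gene(expression: pd.DataFrame, gene: str) -> pd.Series:
    """log2(TPM + 1) for one gene across patients.

    ``expression`` is a genes x patients matrix (gene symbols as index).
    """
    gene = gene.strip()
    if gene not in expression.index:
        raise MissingGeneError(f"gene {gene!r} not found in expression matrix")
    return pd.Series(_log_tpm(expression.loc[gene]), index=expression.columns, name=gene)


def score_gene_set(
    expression: pd.DataFrame, genes: Iterable[str]
) -> tuple[pd.Series, tuple[str, ...]]:
    """Mean log2(TPM + 1) over the member genes present in the matrix.

    Returns the per-patient score and the tuple of member genes that were not
    found (skipped rather than failing: public matrices differ in symbol
    dialects). Raises :class:`MissingSignatureError` when no member is present.
    """
    genes = [g.strip() for g in genes]
    found = [g for g in genes if g in expression.index]
    missing = tuple(g for g in genes if g not in expression.index)
    if not found:
        raise MissingSignatureError(f"none of the signature genes {genes} are present")
    block = np.log2(expression.loc[found].to_numpy(dtype=float) + 1.0)
    return pd.Series(block.mean(axis=0), index=expression.columns), missing


def score_mutational_load(
    mutations: pd.DataFrame | None,
    patient_ids: Sequence[str],
    dedup: bool = False,
) -> pd.Series:
    """Absolute number of somatic variant records per patient.

    Duplicated identical records are counted as listed unless ``dedup`` is set;
    patients without records score 0.
    """
    counts = pd.Series(0, index=pd.Index(patient_ids, name="patient_id"), dtype=int)
    if mutations is None or mutations.empty:
        return counts
    records = mutations.drop_duplicates() if dedup else mutations
    unknown = set(records["patient_id"]) - set(patient_ids)
    if unknown:
        raise IdentifierMismatchError(
            f"mutation records for unknown patients: {sorted(unknown)}"
        )
    tallied = records.groupby("patient_id").size()
    counts.loc[tallied.index] = tallied.astype(int)
    return counts


def assemble_scores(
    bundle,
    panel: Sequence[MarkerDefinition] | None = None,
    plugin_scores: pd.DataFrame | None = None,
    dedup_mutations: bool = False,
) -> MarkerScoreTable:
    """Build the patients x markers score table for one cohort.

    RNA markers are NaN when the cohort has no expression data; plug-in
    markers are taken from ``plugin_scores`` (falling back to
    ``bundle.plugin_scores``) or left NaN.
    """
    defs = list(panel) if panel is not None else builtin_panel()
    patients = list(bundle.clinical["patient_id"])
    if plugin_scores is None:
        plugin_scores = getattr(bundle, "plugin_scores", None)
    if plugin_scores is not None:
        stray = set(plugin_scores.index) - set(patients)
        if stray:
            raise IdentifierMismatchError(
                f"plug-in scores for patients not in cohort "
                f"{bundle.cohort_id}: {sorted(stray)}"
            )

    table = pd.DataFrame(
        np.nan, index=pd.Index(patients, name="patient_id"), columns=[m.name for m in defs]
    )
    missing_report: dict[str, tuple[str, ...]] = {}
    rna = bundle.expression is not None
    dna = bundle.mutations is not None
    for marker in defs:
        if marker.kind == KIND_PLUGIN:
            if plugin_scores is not None and marker.name in plugin_scores.columns:
                table.loc[plugin_scores.index, marker.name] = plugin_scores[marker.name]
            continue
        if marker.origin == ORIGIN_RNA and not rna:
            continue
        if marker.origin == ORIGIN_DNA and not dna:
            continue
        if marker.kind == KIND_SINGLE:
            scores = score_single_gene(bundle.expression, marker.genes[0])
        elif marker.kind == KIND_GENE_SET:
            scores, missing = score_gene_set(bundle.expression, marker.genes)
            if missing:
                missing_report[marker.name] = missing
        else:  # count
            scores = score_mutational_load(
                bundle.mutations, patients, dedup=dedup_mutations
            ).astype(float)
        table.loc[scores.index, marker.name] = scores
    return MarkerScoreTable(scores=table, missing_genes=missing_report)
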