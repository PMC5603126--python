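"""Reading, validation and writing of methylation matrices and phenotype tables.

The on-disk layout follows the TCGA level-3 convention: a tab-delimited
beta-value matrix with probes in rows (first column = probe ID, header row =
sample IDs), a two-column phenotype table mapping each sample to one of four
clinical groups, and an optional two-column probe-to-gene annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Admissible phenotype labels. ``unclassified`` marks tumour samples whose
#: lymph-node status is unknown: they count as cancer in the normal-vs-cancer
#: comparison and are excluded from the LN comparison.
PHENOTYPES = ("normal", "LN_negative", "LN_positive", "unclassified")


class FormatError(ValueError):
    """Malformed input file (ragged rows, duplicate IDs, out-of-range values)."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (empty groups, bad thresholds...)."""


@dataclass(frozen=True)
class ComparisonSpec:
    """A binary sample contrast.

    ``group_a`` is the reference side (normal, or LN-negative) and ``group_b``
    the alternative (cancer, or LN-positive); mean methylation differences are
    reported as ``mean(group_b) - mean(group_a)``.
    """

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ConfigurationError(
                f"comparison {self.name!r}: both groups must be non-empty"
            )
        overlap = set(self.group_a) & set(self.group_b)
        if overlap:
            raise ConfigurationError(
                f"comparison {self.name!r}: groups overlap on {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class FeaturePanel:
    """Final ordered probe set for one comparison.

    Probes are ordered by descending consensus count (ties by probe ID); the
    optional ``genes`` mapping attaches gene symbols per probe.
    """

    comparison: str
    probes: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)
    genes: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.genes.values():
            out |= g
        return frozenset(out)


def _check_unique(ids, kind: str) -> None:
    if pd.Index(ids).has_duplicates:
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise FormatError(f"duplicate {kind} IDs: {dupes[:5]}")


def validate_beta_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a probes x samples beta matrix and drop all-missing rows."""
    _check_unique(matrix.index, "probe")
    _check_unique(matrix.columns, "sample")
    values = matrix.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"beta value out of [0,1]: probe {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}, value {values[i, j]!r}"
        )
    all_na = matrix.isna().all(axis=1)
    if all_na.any():
        logger.info("dropping %d probes with all-missing values", int(all_na.sum()))
        matrix = matrix.loc[~all_na]
    return matrix.astype(float)


def read_beta_matrix(path, known_sample_ids=None) -> pd.DataFrame:
    """Read a TSV beta matrix (probe IDs in first column, sample IDs in header).

    If ``known_sample_ids`` is given and the row index looks like sample IDs
    while the header does not, the file is rejected as transposed rather than
    silently flipped.
    """
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    non_numeric = matrix.select_dtypes(exclude="number").columns
    if len(non_numeric):
        col = non_numeric[0]
        bad = matrix[col][pd.to_numeric(matrix[col], errors="coerce").isna()
                          & matrix[col].notna()]
        raise FormatError(
            f"non-numeric beta value in sample column {col!r}"
            + (f" at probe {bad.index[0]!r}" if len(bad) else "")
        )
    if known_sample_ids is not None:
        known = set(known_sample_ids)
        in_rows = len(known.intersection(matrix.index))
        in_cols = len(known.intersection(matrix.columns))
        if in_rows > in_cols:
            raise FormatError(
                f"{path} looks transposed: {in_rows} known sample IDs found in the "
                "probe column but only "
                f"{in_cols} in the header; expected probes in rows, samples in columns"
            )
    matrix = validate_beta_matrix(matrix)
    matrix.index.name = None
    matrix.columns.name = None
    return matrix


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_phenotype_table(path) -> pd.Series:
    """Read a two-column TSV (sample_id, phenotype) into a Series."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, found {table.shape[1]}")
    table.columns = ["sample_id", "phenotype"]
    _check_unique(table["sample_id"], "sample")
    bad = ~table["phenotype"].isin(PHENOTYPES)
    if bad.any():
        raise FormatError(
            f"unknown phenotype {table.loc[bad, 'phenotype'].iloc[0]!r} "
            f"for sample {table.loc[bad, 'sample_id'].iloc[0]!r}; "
            f"admitted labels: {PHENOTYPES}"
        )
    pheno = table.set_index("sample_id")["phenotype"]
    pheno.index.name = None
    return pheno


def write_phenotype_table(pheno: pd.Series, path) -> None:
    pheno.rename("phenotype").to_csv(path, sep="\t", index_label="sample_id")


def read_probe_annotation(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (probe_id, comma-separated gene symbols)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if table.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, found {table.shape[1]}")
    table.columns = ["probe_id", "genes"]
    _check_unique(table["probe_id"], "probe")
    return {
        row.probe_id: frozenset(g.strip() for g in row.genes.split(",") if g.strip())
        for row in table.itertuples()
    }


def build_comparisons(
    pheno: pd.Series, include_unclassified_in_cancer: bool = True
) -> tuple[ComparisonSpec, ComparisonSpec]:
    """Derive the study's two binary contrasts from the phenotype table.

    Comparison 1 (``normal_vs_cancer``): normal vs all tumour samples
    (LN-negative, LN-positive and, by default, unclassified).
    Comparison 2 (``ln_neg_vs_ln_pos``): LN-negative vs LN-positive tumours;
    unclassified samples are excluded because their node status is unknown.
    """
    if pheno.empty:
        raise ConfigurationError("phenotype table is empty")
    bad = ~pheno.isin(PHENOTYPES)
    if bad.any():
        raise FormatError(f"unknown phenotype label(s): {sorted(pheno[bad].unique())}")
    groups = {p: tuple(pheno.index[pheno == p]) for p in PHENOTYPES}
    cancer = groups["LN_negative"] + groups["LN_positive"]
    if include_unclassified_in_cancer:
        cancer = cancer + groups["unclassified"]
    cmp1 = ComparisonSpec("normal_vs_cancer", groups["normal"], cancer)
    cmp2 = ComparisonSpec("ln_neg_vs_ln_pos", groups["LN_negative"], groups["LN_positive"])
    return cmp1, cmp2


def annotate_probes(
    panel: FeaturePanel, annotation: dict[str, frozenset[str]]
) -> FeaturePanel:
    """Attach gene sets to a panel; probes without an entry map to the empty set."""
    missing = [p for p in panel.probes if p not in annotation]
    if missing:
        logger.info("%d panel probes have no annotation entry", len(missing))
    genes = {p: frozenset(annotation.get(p, frozenset())) for p in panel.probes}
    return replace(panel, genes=genes)
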