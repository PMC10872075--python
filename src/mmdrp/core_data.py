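"""Domain types and file I/O for omic matrices, drug catalogs and response tables.

Cell-line profiling data arrives as delimited text (rows = cell lines, columns
= molecular features); drug catalogs as (name, SMILES, flags) tables; drug
responses as (cell line, drug, AAC, lineage) records where AAC is the area
above the dose-response curve, a [0, 1] efficacy summary (higher = stronger
response).

Standardization is *fold-local*: means and standard deviations are estimated
on the training split of a cross-validation fold only, then applied to both
splits, so no information leaks from validation rows into the transform.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mmdrp")

__all__ = [
    "OmicType", "OmicMatrix", "DrugRecord", "ResponseRecord",
    "StandardizationStats", "load_omic_matrix", "load_drug_catalog",
    "load_response_table", "fit_standardizer", "apply_standardizer",
    "inverse_standardizer",
]


class OmicType(str, enum.Enum):
    """The eight cell-line molecular profiling data types."""

    MUT = "MUT"        # single-nucleotide variation (binary per gene)
    CNV = "CNV"        # copy number variation
    EXP = "EXP"        # gene expression
    PROT = "PROT"      # MS-based quantitative proteomics
    MIRNA = "MIRNA"    # miRNA expression
    METAB = "METAB"    # metabolite abundance
    HIST = "HIST"      # histone H3 modification
    RPPA = "RPPA"      # reverse-phase protein array


@dataclass
class OmicMatrix:
    """One omic data type's cell-line x feature matrix."""

    omic_type: OmicType
    cell_lines: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_lines), len(self.feature_names)):
            raise ValueError(
                f"{self.omic_type.value}: value matrix shape {self.values.shape} "
                f"does not match {len(self.cell_lines)} cell lines x "
                f"{len(self.feature_names)} features"
            )
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError(f"{self.omic_type.value}: duplicate cell-line rows")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row_index(self) -> dict[str, int]:
        return {cl: i for i, cl in enumerate(self.cell_lines)}

    def rows_for(self, cell_lines: list[str]) -> np.ndarray:
        idx = self.row_index()
        return self.values[[idx[cl] for cl in cell_lines]]


@dataclass(frozen=True)
class DrugRecord:
    """A catalog entry: compound name, structure, and annotation flags."""

    name: str
    smiles: str
    targeted: bool = False
    approved_lineages: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ResponseRecord:
    """One (cell line, drug) dose-response experiment summary."""

    cell_line: str
    drug: str
    aac: float
    lineage: str

    def __post_init__(self):
        if not (0.0 <= self.aac <= 1.0):
            raise ValueError(
                f"AAC must lie in [0, 1]; got {self.aac} for "
                f"({self.cell_line}, {self.drug})"
            )


@dataclass
class StandardizationStats:
    """Per-feature mean/sd fitted on a training split only.

    Constant training columns get sd := 1 so the column maps to zero while
    feature indices stay aligned for downstream attribution.
    """

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_omic_matrix(path: str, omic_type: OmicType | str, *,
                     strict: bool = True, delimiter: str | None = None,
                     normalize_ids: bool = False) -> OmicMatrix:
    """Read a delimited cell-line x feature matrix.

    First column = cell-line identifiers, header row = feature names.
    ``strict`` rejects missing cells (naming the offending row/column);
    otherwise they are mean-imputed with a logged count.  ``normalize_ids``
    opt-in strips/uppercases identifiers; matching is exact-string by default.
    """
    omic_type = OmicType(omic_type)
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if normalize_ids:
        df.index = df.index.astype(str).str.strip().str.upper()
    else:
        df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate cell-line rows {dupes}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if np.isnan(values).any():
        rows, cols = np.nonzero(np.isnan(values))
        first = (df.index[rows[0]], df.columns[cols[0]])
        if strict:
            raise ValueError(
                f"{path}: missing value at cell line {first[0]!r}, "
                f"feature {first[1]!r} ({len(rows)} missing total)"
            )
        col_means = np.nanmean(values, axis=0)
        values[np.isnan(values)] = np.take(col_means, cols)
        logger.warning("%s: mean-imputed %d missing cells", path, len(rows))
    if omic_type is OmicType.MUT:
        bad = ~np.isin(values, (0.0, 1.0))
        if bad.any():
            r, c = np.nonzero(bad)
            raise ValueError(
                f"{path}: MUT values must be binary; found {values[r[0], c[0]]} "
                f"at cell line {df.index[r[0]]!r}, gene {df.columns[c[0]]!r}"
            )
    return OmicMatrix(omic_type, df.index.tolist(), df.columns.tolist(), values)


def load_drug_catalog(path: str, *, delimiter: str | None = None) -> list[DrugRecord]:
    """Read a drug catalog: name, SMILES, optional targeted flag and
    semicolon-separated approved lineages."""
    from rdkit import Chem

    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    cols = {c.lower(): c for c in df.columns}
    if "name" not in cols or "smiles" not in cols:
        raise ValueError(f"{path}: catalog needs 'name' and 'smiles' columns")
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = str(row[cols["name"]])
        if name in seen:
            raise ValueError(f"{path}: duplicate drug name {name!r}")
        seen.add(name)
        smiles = str(row[cols["smiles"]])
        if Chem.MolFromSmiles(smiles) is None:
            raise ValueError(f"{path}: SMILES for {name!r} does not parse: {smiles!r}")
        targeted = bool(row[cols["targeted"]]) if "targeted" in cols else False
        lineages: frozenset[str] = frozenset()
        if "approved_lineages" in cols and not pd.isna(row[cols["approved_lineages"]]):
            raw = str(row[cols["approved_lineages"]])
            lineages = frozenset(s for s in raw.split(";") if s)
        records.append(DrugRecord(name, smiles, targeted, lineages))
    return records


def load_response_table(path: str, *, delimiter: str | None = None) -> list[ResponseRecord]:
    """Read (cell_line, drug, aac, lineage) records from delimited text."""
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    cols = {c.lower(): c for c in df.columns}
    needed = ("cell_line", "drug", "aac", "lineage")
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"{path}: response table missing columns {missing}")
    return [
        ResponseRecord(str(r[cols["cell_line"]]), str(r[cols["drug"]]),
                       float(r[cols["aac"]]), str(r[cols["lineage"]]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# fold-local standardization
# ---------------------------------------------------------------------------

def fit_standardizer(matrix: OmicMatrix, train_rows) -> StandardizationStats:
    """Estimate per-feature mean/sd from ``train_rows`` only.

    ``train_rows`` is an index set into ``matrix.cell_lines``. Sample (ddof=1)
    standard deviation; columns constant on the training rows get sd := 1.
    """
    train_rows = sorted(set(int(i) for i in train_rows))
    if not train_rows:
        raise ValueError("empty training row set")
    if train_rows[0] < 0 or train_rows[-1] >= len(matrix.cell_lines):
        raise IndexError("train_rows out of range")
    sub = matrix.values[train_rows]
    mean = sub.mean(axis=0)
    std = sub.std(axis=0, ddof=1) if len(train_rows) > 1 else np.zeros(sub.shape[1])
    std = np.where(std > 0, std, 1.0)
    return StandardizationStats(list(matrix.feature_names), mean, std)


def apply_standardizer(matrix: OmicMatrix, stats: StandardizationStats) -> OmicMatrix:
    """Transform every row by ``(x - mean) / sd`` (train and validation alike)."""
    if stats.feature_names != matrix.feature_names:
        raise ValueError(
            f"{matrix.omic_type.value}: standardizer feature names do not match matrix"
        )
    values = (matrix.values - stats.mean) / stats.std
    return OmicMatrix(matrix.omic_type, list(matrix.cell_lines),
                      list(matrix.feature_names), values)


def inverse_standardizer(matrix: OmicMatrix, stats: StandardizationStats) -> OmicMatrix:
    """Undo :func:`apply_standardizer` (exact algebraic inverse)."""
    if stats.feature_names != matrix.feature_names:
        raise ValueError("standardizer feature names do not match matrix")
    values = matrix.values * stats.std + stats.mean
    return OmicMatrix(matrix.omic_type, list(matrix.cell_lines),
                      list(matrix.feature_names), values)
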