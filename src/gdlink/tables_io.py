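"""Readers, validators and filters for the three input tables.

The pipeline consumes three tab-separated inputs:

* a gene-disease association table (DisGeNET-style export) with per-row
  disease typing, the Disease Specificity Index (DSI), the Disease
  Pleiotropy Index (DPI) and the year the association was first reported;
* a gene-tissue expression table (Human Protein Atlas-style export) with
  per-cell-type expression level and reliability calls;
* a dense gene-by-gene co-expression similarity matrix (ARCHS4-style
  pairwise Pearson correlations).

Column names vary across database versions, so every reader takes a
:class:`TableDialect` mapping canonical field names to the column headers
actually present in the file; matching is case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DISEASE_TYPES = {"disease", "phenotype", "group"}
EXPRESSION_LEVELS = {"high", "medium", "low", "not detected"}
RELIABILITIES = {"approved", "enhanced", "supported", "uncertain"}

#: semantic type retained by :func:`filter_associations`
DISEASE_OR_SYNDROME = "Disease or Syndrome"

SYMMETRY_TOL = 1e-9
DIAGONAL_TOL = 1e-9


class TableError(ValueError):
    """Malformed or unreadable input table."""


@dataclass(frozen=True)
class AssociationRecord:
    """One curated gene-disease association row.

    ``dsi`` (in [0.25, 1]; low for promiscuous genes) and ``dpi``
    (in [0, 1]; high for genes whose diseases span many MeSH classes)
    may be missing (``None``), as real exports contain NA values.
    """

    gene_symbol: str
    disease_id: str
    disease_name: str
    disease_type: str
    semantic_type: str
    dsi: float | None = None
    dpi: float | None = None
    year_initial: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbol or not self.disease_id:
            raise TableError("gene_symbol and disease_id must be non-empty")
        if self.disease_type not in DISEASE_TYPES:
            raise TableError(f"unknown disease_type {self.disease_type!r}")
        if self.dsi is not None and not (0.25 <= self.dsi <= 1.0):
            raise TableError(f"DSI {self.dsi} outside [0.25, 1]")
        if self.dpi is not None and not (0.0 <= self.dpi <= 1.0):
            raise TableError(f"DPI {self.dpi} outside [0, 1]")


@dataclass(frozen=True)
class TissueRecord:
    """One gene-tissue-cell-type expression call."""

    gene_id: str
    tissue: str
    cell_type: str
    expression_level: str
    reliability: str

    def __post_init__(self) -> None:
        if self.expression_level.lower() not in EXPRESSION_LEVELS:
            raise TableError(f"unknown expression level {self.expression_level!r}")
        if self.reliability.lower() not in RELIABILITIES:
            raise TableError(f"unknown reliability {self.reliability!r}")


@dataclass
class CoexpressionMatrix:
    """Symmetric gene-by-gene similarity matrix with a label index.

    Entries are Pearson correlations in [-1, 1] with a unit diagonal.
    """

    gene_index: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_index)
        if self.values.shape != (n, n):
            raise TableError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.gene_index)) != n:
            raise TableError("duplicate gene labels in co-expression matrix")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise TableError(f"matrix asymmetry {asym:.3e} exceeds tolerance")
        self.values = (self.values + self.values.T) / 2.0
        if n and np.max(np.abs(np.diag(self.values) - 1.0)) > DIAGONAL_TOL:
            raise TableError("diagonal entries must equal 1")
        if n and (self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12):
            raise TableError("similarity entries must lie in [-1, 1]")
        self._pos = {g: i for i, g in enumerate(self.gene_index)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos

    def __len__(self) -> int:
        return len(self.gene_index)

    def position(self, gene: str) -> int:
        return self._pos[gene]

    def similarity(self, a: str, b: str) -> float:
        return float(self.values[self._pos[a], self._pos[b]])


@dataclass(frozen=True)
class TableDialect:
    """Canonical-field-to-column-header mapping for the tabular inputs.

    Defaults follow the DisGeNET / Human Protein Atlas export headers.
    Header matching is case-insensitive.
    """

    association_columns: dict = field(
        default_factory=lambda: {
            "gene_symbol": "geneSymbol",
            "disease_id": "diseaseId",
            "disease_name": "diseaseName",
            "disease_type": "diseaseType",
            "semantic_type": "diseaseSemanticType",
            "dsi": "DSI",
            "dpi": "DPI",
            "year_initial": "YearInitial",
        }
    )
    tissue_columns: dict = field(
        default_factory=lambda: {
            "gene_id": "Gene",
            "tissue": "Tissue",
            "cell_type": "Cell type",
            "expression_level": "Level",
            "reliability": "Reliability",
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dialect = cls()
        if "association_columns" in raw:
            dialect = replace(
                dialect,
                association_columns={
                    **dialect.association_columns,
                    **raw["association_columns"],
                },
            )
        if "tissue_columns" in raw:
            dialect = replace(
                dialect,
                tissue_columns={**dialect.tissue_columns, **raw["tissue_columns"]},
            )
        return dialect


DEFAULT_DIALECT = TableDialect()


def _resolve_columns(header: Sequence[str], wanted: dict, path: Path) -> dict:
    """Map canonical field names to actual header names, case-insensitively."""
    lower = {str(h).strip().lower(): h for h in header}
    resolved = {}
    for fieldname, colname in wanted.items():
        key = colname.strip().lower()
        if key not in lower:
            raise TableError(f"{path}: missing mandatory column {colname!r}")
        resolved[fieldname] = lower[key]
    return resolved


def _clean_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _clean_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    v = float(value)
    return None if np.isnan(v) else v


def read_associations(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[AssociationRecord]:
    """Read a gene-disease association TSV into validated records.

    Rows with malformed mandatory fields are dropped with a logged,
    row-numbered diagnostic rather than aborting the whole read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise TableError(f"{path}: empty association table")
    cols = _resolve_columns(df.columns, dialect.association_columns, path)
    records: list[AssociationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            year = _clean_float(row_d[cols["year_initial"]])
            rec = AssociationRecord(
                gene_symbol=_clean_str(row_d[cols["gene_symbol"]]) or "",
                disease_id=_clean_str(row_d[cols["disease_id"]]) or "",
                disease_name=_clean_str(row_d[cols["disease_name"]]) or "",
                disease_type=(_clean_str(row_d[cols["disease_type"]]) or "").lower(),
                semantic_type=_clean_str(row_d[cols["semantic_type"]]) or "",
                dsi=_clean_float(row_d[cols["dsi"]]),
                dpi=_clean_float(row_d[cols["dpi"]]),
                year_initial=None if year is None else int(year),
            )
        except (TableError, ValueError) as exc:
            logger.warning("%s row %d rejected: %s", path.name, i + 2, exc)
            continue
        records.append(rec)
    return records


def write_associations(
    records: Iterable[AssociationRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    cols = dialect.association_columns
    rows = [
        {
            cols["gene_symbol"]: r.gene_symbol,
            cols["disease_id"]: r.disease_id,
            cols["disease_name"]: r.disease_name,
            cols["disease_type"]: r.disease_type,
            cols["semantic_type"]: r.semantic_type,
            cols["dsi"]: r.dsi,
            cols["dpi"]: r.dpi,
            cols["year_initial"]: r.year_initial,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tissue(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[TissueRecord]:
    """Read a gene-tissue expression TSV into validated records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise TableError(f"{path}: empty tissue table")
    cols = _resolve_columns(df.columns, dialect.tissue_columns, path)
    records: list[TissueRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            rec = TissueRecord(
                gene_id=_clean_str(row_d[cols["gene_id"]]) or "",
                tissue=_clean_str(row_d[cols["tissue"]]) or "",
                cell_type=_clean_str(row_d[cols["cell_type"]]) or "",
                expression_level=_clean_str(row_d[cols["expression_level"]]) or "",
                reliability=_clean_str(row_d[cols["reliability"]]) or "",
            )
            if not rec.gene_id or not rec.tissue or not rec.cell_type:
                raise TableError("empty gene/tissue/cell_type field")
        except (TableError, ValueError) as exc:
            logger.warning("%s row %d rejected: %s", path.name, i + 2, exc)
            continue
        records.append(rec)
    return records


def write_tissue(
    records: Iterable[TissueRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    cols = dialect.tissue_columns
    rows = [
        {
            cols["gene_id"]: r.gene_id,
            cols["tissue"]: r.tissue,
            cols["cell_type"]: r.cell_type,
            cols["expression_level"]: r.expression_level,
            cols["reliability"]: r.reliability,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_associations(
    records: Iterable[AssociationRecord],
) -> list[AssociationRecord]:
    """Apply the association inclusion rules.

    Keeps rows typed as a genuine disease (``disease_type == 'disease'``
    and semantic type 'Disease or Syndrome'), then drops every disease
    left with fewer than two distinct genes. Idempotent.
    """
    kept = [
        r
        for r in records
        if r.disease_type == "disease"
        and r.semantic_type.strip().lower() == DISEASE_OR_SYNDROME.lower()
    ]
    genes_per_disease: dict[str, set[str]] = {}
    for r in kept:
        genes_per_disease.setdefault(r.disease_id, set()).add(r.gene_symbol)
    return [r for r in kept if len(genes_per_disease[r.disease_id]) >= 2]


def filter_tissue(records: Iterable[TissueRecord]) -> list[tuple[str, str]]:
    """Apply the tissue inclusion rules and return unique (gene, tissue) pairs.

    Keeps only High-level, Approved-reliability calls, then requires each
    (gene, tissue) pair to be observed in at least two distinct cell types.
    """
    cell_types: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.reliability.strip().lower() != "approved":
            continue
        if r.expression_level.strip().lower() != "high":
            continue
        cell_types.setdefault((r.gene_id, r.tissue), set()).add(r.cell_type)
    return sorted(pair for pair, cts in cell_types.items() if len(cts) >= 2)


def read_coexpression(path: str | Path) -> CoexpressionMatrix:
    """Read a dense labeled co-expression matrix (TSV, labels in row 1/col 1).

    Asymmetry up to ``SYMMETRY_TOL`` is silently repaired by averaging
    with the transpose; anything larger is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(g) for g in df.index]
    if [str(c) for c in df.columns] != labels:
        raise TableError(f"{path}: row and column labels differ or matrix not square")
    return CoexpressionMatrix(gene_index=labels, values=df.to_numpy(dtype=float))


def write_coexpression(matrix: CoexpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.values, index=matrix.gene_index, columns=matrix.gene_index
    ).to_csv(path, sep="\t")
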