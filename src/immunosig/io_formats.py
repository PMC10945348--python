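"""Readers and writers for every external artifact the pipeline touches.

Formats: Matrix Market coordinate files with gene/cell TSV sidecars,
GMT gene-set files, samples x genes expression CSV, and a clinical TSV
with fixed columns (sample_id, response, batch, os_time, os_event).
All writers round-trip bit-stably through their paired reader.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from immunosig.errors import FormatError, ValidationError

VALID_RESPONSES = ("PD", "NPD")

CLINICAL_COLUMNS = ["sample_id", "response", "batch", "os_time", "os_event"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Sparse non-negative genes x cells matrix with identifier lists.

    ``layer_tag`` records whether values are raw counts (``"counts"``)
    or log-normalized expression (``"lognorm"``).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative matrix entries")
        if self.layer_tag not in ("counts", "lognorm"):
            raise ValidationError(f"unknown layer tag {self.layer_tag!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset(
        self,
        genes: Sequence[str] | None = None,
        cells: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given identifiers (order kept)."""
        gidx = (
            np.arange(self.n_genes)
            if genes is None
            else np.array([self.gene_ids.index(g) for g in genes])
        )
        cidx = (
            np.arange(self.n_cells)
            if cells is None
            else np.array([self.cell_ids.index(c) for c in cells])
        )
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in gidx],
            cell_ids=[self.cell_ids[i] for i in cidx],
            counts=self.counts[gidx, :][:, cidx],
            layer_tag=self.layer_tag,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.layer_tag == other.layer_tag
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class GeneSignature:
    """A named, ordered, duplicate-free gene list with provenance."""

    name: str
    genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class BulkCohort:
    """Bulk expression (samples x genes) aligned with a clinical table."""

    expression: pd.DataFrame  # index = sample_id, columns = gene ids
    clinical: pd.DataFrame  # columns per CLINICAL_COLUMNS, index = sample_id

    def __post_init__(self) -> None:
        if list(self.expression.index) != list(self.clinical.index):
            raise ValidationError("expression and clinical sample order differ")
        validate_clinical(self.clinical.reset_index())

    @property
    def samples(self) -> list[str]:
        return list(self.expression.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def response(self) -> pd.Series:
        return self.clinical["response"]

    def subset_samples(self, samples: Sequence[str]) -> "BulkCohort":
        samples = list(samples)
        return BulkCohort(
            expression=self.expression.loc[samples].copy(),
            clinical=self.clinical.loc[samples].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BulkCohort):
            return NotImplemented
        return self.expression.equals(other.expression) and self.clinical.equals(
            other.clinical
        )


# ---------------------------------------------------------------------------
# Chromosome ordering & gene annotation
# ---------------------------------------------------------------------------

_DEFAULT_CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]


def _strip_chr(name: str) -> str:
    return re.sub(r"^chr", "", str(name), flags=re.IGNORECASE)


def chromosome_sort_key(chromosome: str, order: Sequence[str] | None = None):
    """Sort key implementing the natural 1..22, X, Y, MT ordering.

    Unknown chromosomes sort after the known ones, alphabetically.
    """
    order = list(order) if order is not None else _DEFAULT_CHROM_ORDER
    name = _strip_chr(chromosome)
    if name in order:
        return (0, order.index(name), "")
    return (1, 0, name)


def validate_gene_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check and coerce a gene annotation table (gene_id, chromosome, start[, is_mito])."""
    required = {"gene_id", "chromosome", "start"}
    missing = required - set(annotation.columns)
    if missing:
        raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
    annotation = annotation.copy()
    if annotation["gene_id"].duplicated().any():
        dupes = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"]
        raise ValidationError(f"duplicate gene ids in annotation: {list(dupes[:5])}")
    annotation["start"] = annotation["start"].astype(int)
    if (annotation["start"] < 1).any():
        raise ValidationError("gene start positions must be 1-based (>= 1)")
    if "is_mito" not in annotation.columns:
        annotation["is_mito"] = annotation["gene_id"].str.startswith("MT-")
    annotation["is_mito"] = annotation["is_mito"].astype(bool)
    return annotation


def sort_genes_by_position(
    annotation: pd.DataFrame, chrom_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Return the annotation sorted by (chromosome, start) under the declared ordering."""
    annotation = validate_gene_annotation(annotation)
    keys = annotation["chromosome"].map(
        lambda c: chromosome_sort_key(c, chrom_order)
    )
    order = sorted(
        range(len(annotation)),
        key=lambda i: (keys.iloc[i], annotation["start"].iloc[i]),
    )
    return annotation.iloc[order].reset_index(drop=True)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table against the fixed schema."""
    missing = set(CLINICAL_COLUMNS) - set(clinical.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    clinical = clinical.copy()
    bad = set(clinical["response"].unique()) - set(VALID_RESPONSES)
    if bad:
        raise ValidationError(
            f"invalid response labels {sorted(bad)}; expected one of {VALID_RESPONSES}"
        )
    clinical["os_time"] = clinical["os_time"].astype(float)
    clinical["os_event"] = clinical["os_event"].astype(int)
    if (clinical["os_time"] < 0).any():
        raise ValidationError("negative survival times")
    if not set(clinical["os_event"].unique()) <= {0, 1}:
        raise ValidationError("os_event must be 0/1")
    if clinical["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in clinical table")
    return clinical


# ---------------------------------------------------------------------------
# Matrix Market + sidecars
# ---------------------------------------------------------------------------


def read_expression_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    layer_tag: str = "counts",
) -> ExpressionMatrix:
    """Read a Matrix Market coordinate file with gene/cell sidecar TSVs.

    The sidecars are one identifier per line (first tab-separated field).
    Output is independent of triplet line order.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises ValueError on malformed files
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}")
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {mat.shape} but sidecars declare "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return ExpressionMatrix(genes, cells, mat, layer_tag=layer_tag)


def write_expression_mtx(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(matrix.counts))
    Path(genes_path).write_text("".join(g + "\n" for g in matrix.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in matrix.cell_ids))


def _read_id_column(path: str | Path) -> list[str]:
    ids = [
        line.split("\t")[0]
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate identifiers in {path}")
    return ids


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file: one tab-separated line per set (name, description, genes...)."""
    signatures = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        name, description = fields[0], fields[1]
        genes, seen = [], set()
        for g in fields[2:]:
            if not g:
                continue
            if g in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate gene {g!r} in set {name!r} collapsed"
                )
                continue
            seen.add(g)
            genes.append(g)
        signatures.append(
            GeneSignature(name, tuple(genes), provenance={"description": description})
        )
    return signatures


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    lines = []
    for sig in signatures:
        desc = str(sig.provenance.get("description", ""))
        lines.append("\t".join([sig.name, desc, *sig.genes]))
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------


def read_bulk_cohort(
    expr_csv: str | Path,
    clinical_tsv: str | Path,
    log_transform: bool = False,
) -> BulkCohort:
    """Load a bulk cohort, restricting to samples present in both tables.

    Expression CSV: first column sample_id, remaining columns gene ids.
    ``log_transform=True`` applies log1p for cohorts delivered on a raw scale.
    """
    expr = pd.read_csv(expr_csv, index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = None
    clinical = pd.read_csv(clinical_tsv, sep="\t", dtype={"sample_id": str})
    clinical = validate_clinical(clinical)
    clinical = clinical.set_index("sample_id", drop=False)

    shared = [s for s in expr.index if s in set(clinical.index)]
    if not shared:
        raise ValidationError("no overlapping samples between expression and clinical")
    dropped = (set(expr.index) | set(clinical.index)) - set(shared)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} samples absent from one of the two tables: "
            f"{sorted(dropped)[:10]}"
        )
    expr = expr.loc[shared]
    if log_transform:
        expr = np.log1p(expr)
    clinical = clinical.loc[shared]
    clinical.index.name = None
    return BulkCohort(expression=expr, clinical=clinical)


def write_bulk_cohort(
    cohort: BulkCohort, expr_csv: str | Path, clinical_tsv: str | Path
) -> None:
    expr = cohort.expression.copy()
    expr.index.name = "sample_id"
    expr.to_csv(expr_csv)
    cohort.clinical.to_csv(clinical_tsv, sep="\t", index=False)
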