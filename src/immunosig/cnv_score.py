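"""Moving-average copy-number inference from expression, with reference centering.

Per cell: reference-subtracted lognorm expression is smoothed along
the genome with a symmetric window per chromosome, recentered by the
cell's genome-wide mean, clipped, and reduced to a scalar score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from immunosig.errors import ValidationError
from immunosig.io_formats import (
    ExpressionMatrix,
    sort_genes_by_position,
)


@dataclass
class CnvConfig:
    window: int = 100
    expression_cutoff: float = 0.1
    reference_label: str = "CD8T"
    clip: float = 3.0
    score_method: str = "mean_square"  # or "mean_abs"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")
        if self.expression_cutoff < 0:
            raise ValidationError("cutoff must be >= 0")
        if self.score_method not in ("mean_square", "mean_abs"):
            raise ValidationError(f"unknown score method {self.score_method!r}")


@dataclass
class CnvProfile:
    cell_ids: list[str]
    genes: list[str]  # retained genes in genomic order
    chromosomes: list[str]  # parallel to genes
    values: np.ndarray  # cells x positions, centered moving averages
    scores: pd.Series = field(default=None)  # per-cell scalar

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.genes)):
            raise ValidationError("profile shape mismatch")


def select_cnv_genes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Genes with mean lognorm expression >= cutoff, in (chromosome, start) order.

    Returns the sorted annotation rows of the retained genes. Genes
    absent from the annotation are dropped with a warning.
    """
    if matrix.layer_tag != "lognorm":
        raise ValidationError("select_cnv_genes expects lognorm layer")
    sorted_ann = sort_genes_by_position(annotation)
    covered = set(sorted_ann["gene_id"])
    uncovered = [g for g in matrix.gene_ids if g not in covered]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} matrix genes missing from annotation, dropped"
        )
    mean_expr = pd.Series(
        np.asarray(matrix.counts.mean(axis=1)).ravel(), index=matrix.gene_ids
    )
    retained = sorted_ann[
        sorted_ann["gene_id"].map(
            lambda g: g in mean_expr.index and mean_expr[g] >= cutoff
        )
    ].reset_index(drop=True)
    if retained.empty:
        raise ValidationError("no genes pass the expression cutoff")
    return retained


def _chromosome_window(n_genes: int, window: int) -> int:
    """Effective window for a chromosome block; shrinks on small blocks, forced odd."""
    w = window if n_genes >= window else max(3, n_genes // 10)
    w = min(w, n_genes)
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Symmetric moving average along axis 1, truncated at the block ends."""
    n = block.shape[1]
    half = window // 2
    csum = np.zeros((block.shape[0], n + 1))
    np.cumsum(block, axis=1, out=csum[:, 1:])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1) + 1
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def infer_cnv_profile(
    matrix: ExpressionMatrix,
    retained_annotation: pd.DataFrame,
    config: CnvConfig,
    reference_cells: list[str],
) -> CnvProfile:
    """Reference-centered moving-average CNV values plus per-cell scores.

    Steps: subtract the reference-cell mean per gene; smooth with a
    symmetric moving window per chromosome (never spanning chromosome
    boundaries); subtract each cell's genome-wide mean of the smoothed
    values; clip to +/- config.clip; score.
    """
    if matrix.layer_tag != "lognorm":
        raise ValidationError("infer_cnv_profile expects lognorm layer")
    if not reference_cells:
        raise ValidationError("empty reference cell set")
    missing = set(reference_cells) - set(matrix.cell_ids)
    if missing:
        raise ValidationError(f"reference cells not in matrix: {sorted(missing)[:5]}")

    genes = list(retained_annotation["gene_id"])
    chroms = [str(c) for c in retained_annotation["chromosome"]]
    sub = matrix.subset(genes=genes)
    dense = sub.dense().T  # cells x genes
    ref_idx = [sub.cell_ids.index(c) for c in reference_cells]
    relative = dense - dense[ref_idx].mean(axis=0)

    smoothed = np.empty_like(relative)
    chrom_arr = np.array(chroms)
    pos = 0
    for chrom in pd.unique(chrom_arr):
        block_idx = np.flatnonzero(chrom_arr == chrom)
        w = _chromosome_window(len(block_idx), config.window)
        smoothed[:, block_idx] = _moving_average(relative[:, block_idx], w)
        pos += len(block_idx)

    centered = smoothed - smoothed.mean(axis=1, keepdims=True)
    centered = np.clip(centered, -config.clip, config.clip)
    profile = CnvProfile(
        cell_ids=list(sub.cell_ids),
        genes=genes,
        chromosomes=chroms,
        values=centered,
    )
    profile.scores = cnv_cell_score(profile, method=config.score_method)
    return profile


def cnv_cell_score(profile: CnvProfile, method: str = "mean_square") -> pd.Series:
    """Scalar CNV burden per cell: mean of squares (default) or mean |value|."""
    if method == "mean_square":
        scores = (profile.values**2).mean(axis=1)
    elif method == "mean_abs":
        scores = np.abs(profile.values).mean(axis=1)
    else:
        raise ValidationError(f"unknown score method {method!r}")
    return pd.Series(scores, index=profile.cell_ids, name="cnv_score")
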