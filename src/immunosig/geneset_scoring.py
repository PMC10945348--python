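"""Per-cell functional gene-set scores with bin-matched control genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from immunosig.errors import ValidationError
from immunosig.io_formats import ExpressionMatrix, GeneSignature
from immunosig.sc_core import compare_groups


@dataclass
class ScoreMatrix:
    """cells x score-names table plus the provenance of each score."""

    values: pd.DataFrame  # index = cell ids, columns = score names
    provenance: dict = field(default_factory=dict)


def module_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean set-gene expression minus mean of expression-bin-matched controls.

    Genes are binned by their population-average lognorm expression
    into ``n_bins`` equal-size bins; each set gene contributes
    ``n_ctrl`` control genes sampled (with replacement) from its own
    bin. Missing set genes are dropped with a warning; an entirely
    absent set is an error. Seeded and deterministic.
    """
    if matrix.layer_tag != "lognorm":
        raise ValidationError("module_score expects lognorm layer")
    present = [g for g in gene_set.genes if g in set(matrix.gene_ids)]
    absent = set(gene_set.genes) - set(present)
    if not present:
        raise ValidationError(f"gene set {gene_set.name!r} entirely absent from matrix")
    if absent:
        warnings.warn(
            f"{len(absent)} genes of set {gene_set.name!r} absent from matrix, dropped"
        )

    dense = matrix.dense()  # genes x cells
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    avg = dense.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    n_genes = len(avg)
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.arange(n_genes) * min(n_bins, n_genes) // n_genes

    rng = np.random.default_rng(seed)
    set_idx = np.array([gene_index[g] for g in present])
    ctrl_rows = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)

    score = dense[set_idx].mean(axis=0) - dense[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=matrix.cell_ids, name=gene_set.name)


def score_gene_sets(
    matrix: ExpressionMatrix,
    gene_sets: list[GeneSignature],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreMatrix:
    """module_score for several sets, assembled into a ScoreMatrix."""
    cols = {
        s.name: module_score(matrix, s, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for s in gene_sets
    }
    values = pd.DataFrame(cols, index=matrix.cell_ids)
    provenance = {
        s.name: {
            "genes": list(s.genes),
            "method": "bin_matched_control",
            "n_bins": n_bins,
            "n_ctrl": n_ctrl,
            "seed": seed,
        }
        for s in gene_sets
    }
    return ScoreMatrix(values=values, provenance=provenance)


def rank_subgroups_by_score(
    scores: pd.Series,
    labels: pd.Series,
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subgroup means/ranks for one score, plus pairwise comparison p-values.

    Subgroups with fewer than ``min_cells`` cells are excluded with a
    warning. Returns (ranking table, pairwise test table); the
    pairwise table is empty when fewer than two subgroups qualify.
    """
    labels = labels.reindex(scores.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_cells].index
    dropped = sizes[sizes < min_cells].index
    if len(dropped):
        warnings.warn(f"excluding subgroups with < {min_cells} cells: {list(dropped)}")
    if len(keep) == 0:
        raise ValidationError("no subgroup has enough cells")

    means = {g: scores[labels == g].mean() for g in keep}
    ranking = (
        pd.DataFrame(
            {"subgroup": list(means), "mean_score": list(means.values()),
             "n_cells": [int(sizes[g]) for g in means]}
        )
        .sort_values("mean_score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    rows = []
    groups = list(ranking["subgroup"])
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            res = compare_groups(scores[labels == a].values, scores[labels == b].values)
            rows.append((a, b, res.test_name, res.statistic, res.p_value))
    pairwise = pd.DataFrame(
        rows, columns=["subgroup_a", "subgroup_b", "test", "statistic", "p_value"]
    )
    return ranking, pairwise
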