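"""Single-cell QC, normalization, clustering, marker derivation and group tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from immunosig.errors import DegenerateInputError, ValidationError
from immunosig.io_formats import ExpressionMatrix, validate_gene_annotation

EXACT_WILCOXON_MAX_N = 8


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    n_cells_in: int
    n_genes_in: int
    removed_low_genes: int
    removed_high_genes: int
    removed_mito: int
    removed_rare_genes: int
    n_cells_out: int
    n_genes_out: int


def qc_filter(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.10,
    min_cells_per_gene: int = 3,
) -> tuple[ExpressionMatrix, pd.DataFrame, QcReport]:
    """Remove low-quality cells and rarely detected genes.

    Cells are dropped when their detected-gene count falls outside
    [min_genes, max_genes] or their mitochondrial count fraction
    exceeds max_mito; genes expressed in fewer than
    ``min_cells_per_gene`` surviving cells are dropped afterwards.
    """
    if matrix.layer_tag != "counts":
        raise ValidationError("qc_filter expects the raw counts layer")
    annotation = validate_gene_annotation(annotation)
    ann = annotation.set_index("gene_id").reindex(matrix.gene_ids)
    if ann["chromosome"].isna().any():
        missing = ann.index[ann["chromosome"].isna()]
        raise ValidationError(f"genes missing from annotation: {list(missing[:5])}")

    counts = sp.csc_matrix(matrix.counts)
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    mito_mask = ann["is_mito"].values.astype(bool)
    mito_totals = np.asarray(counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    low = detected < min_genes
    high = detected > max_genes
    mito_bad = pct_mito > max_mito
    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise ValidationError("QC removed every cell")

    kept = counts[:, keep_cells]
    cells_per_gene = np.asarray((kept > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene

    out = ExpressionMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep_genes) if k],
        cell_ids=[c for c, k in zip(matrix.cell_ids, keep_cells) if k],
        counts=sp.csr_matrix(kept[keep_genes]),
        layer_tag="counts",
    )
    cell_ann = pd.DataFrame(
        {
            "cell_id": out.cell_ids,
            "n_genes_detected": detected[keep_cells].astype(int),
            "pct_mito": pct_mito[keep_cells],
        }
    )
    report = QcReport(
        n_cells_in=matrix.n_cells,
        n_genes_in=matrix.n_genes,
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_mito=int((mito_bad & ~low & ~high).sum()),
        removed_rare_genes=int((~keep_genes).sum()),
        n_cells_out=out.n_cells,
        n_genes_out=out.n_genes,
    )
    return out, cell_ann, report


def normalize_lognorm(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per cell: x -> ln(1 + scale * x / total_counts)."""
    if matrix.layer_tag != "counts":
        raise ValidationError("normalize_lognorm expects the counts layer")
    counts = sp.csc_matrix(matrix.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValidationError("cells with zero total counts; run QC first")
    normed = counts.multiply(scale / totals)  # broadcasts over columns
    normed = normed.log1p()
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        counts=sp.csr_matrix(normed),
        layer_tag="lognorm",
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _select_hvg(dense: np.ndarray, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    """Top genes by binned dispersion z-score (dispersion = var/mean)."""
    mean = dense.mean(axis=1)
    var = dense.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.arange(len(mean)) * n_bins // max(len(mean), 1)
    z = np.zeros(len(mean))
    for b in np.unique(bins):
        mask = bins == b
        mu, sd = disp[mask].mean(), disp[mask].std()
        z[mask] = (disp[mask] - mu) / sd if sd > 0 else 0.0
    n_hvg = min(n_hvg, len(mean))
    return np.sort(np.argsort(-z, kind="stable")[:n_hvg])


def cluster_cells(
    matrix: ExpressionMatrix,
    n_pcs: int = 30,
    n_hvg: int = 2000,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Graph-based clustering of PCA-reduced lognorm expression.

    Variable-gene selection, per-gene scaling, PCA to ``n_pcs``
    components, a shared-nearest-neighbor graph with Jaccard weights,
    then modularity-optimizing community detection (Leiden,
    RBConfiguration at the given resolution). Deterministic for a
    fixed seed.

    Returns integer cluster labels indexed by cell id.
    """
    if matrix.layer_tag != "lognorm":
        raise ValidationError("cluster_cells expects lognorm layer")
    if matrix.n_cells < 2:
        raise ValidationError("need at least 2 cells")
    dense = matrix.dense()
    hvg_idx = _select_hvg(dense, n_hvg)
    x = dense[hvg_idx].T  # cells x genes
    sd = x.std(axis=0)
    mean = x.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    x = np.clip(x, -10, 10)

    max_pcs = min(x.shape) - 1
    if n_pcs >= min(x.shape):
        raise ValidationError(
            f"n_pcs={n_pcs} must be below min(n_cells, n_genes)={min(x.shape)}"
        )
    n_pcs = min(n_pcs, max_pcs)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(x)
    # fix component signs for run-to-run bit stability
    signs = np.sign(pca.components_[np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)])
    signs[signs == 0] = 1.0
    emb = emb * signs

    k = min(n_neighbors, matrix.n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neighbor_sets = [set(row[1:]) | {i} for i, row in enumerate(idx)]

    pairs = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            j = int(j)
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    edges, weights = [], []
    for i, j in sorted(pairs):
        shared = len(neighbor_sets[i] & neighbor_sets[j])
        union = len(neighbor_sets[i] | neighbor_sets[j])
        w = shared / union
        if w > 0:
            edges.append((i, j))
            weights.append(w)
    graph = igraph.Graph(n=matrix.n_cells, edges=edges)
    graph.es["weight"] = weights
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return pd.Series(part.membership, index=matrix.cell_ids, name="cluster")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test.

    Exact permutation enumeration when both groups have <= 8
    observations (correct under ties); otherwise the normal
    approximation with tie correction. Returns (z_or_ranksum
    statistic, p). The statistic is the standardized rank sum of ``x``
    (0 for the degenerate all-tied case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("empty group in rank-sum test")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0

    if n1 <= EXACT_WILCOXON_MAX_N and n2 <= EXACT_WILCOXON_MAX_N:
        total = comb(n, n1)
        lo = hi = 0
        for combo in combinations(range(n), n1):
            s = ranks[list(combo)].sum()
            if s <= w + 1e-9:
                lo += 1
            if s >= w - 1e-9:
                hi += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
        sd = np.sqrt(max(_ranksum_var(ranks, n1, n2), 0.0))
        z = (w - mu) / sd if sd > 0 else 0.0
        return z, p

    var = _ranksum_var(ranks, n1, n2)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    return z, float(min(1.0, 2.0 * scipy.stats.norm.sf(abs(z))))


def _ranksum_var(ranks: np.ndarray, n1: int, n2: int) -> float:
    """Tie-corrected variance of the rank sum."""
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / ((n) * (n - 1)) if n > 1 else 0.0
    return n1 * n2 / 12.0 * ((n + 1) - tie_term)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------


def find_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    cluster,
    min_logfc: float = 0.25,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum marker test of one cluster against all remaining cells.

    log_fc = ln(mean(expm1(in)) + 1) - ln(mean(expm1(out)) + 1) on the
    lognorm layer. Rows kept when log_fc > min_logfc and p < max_p; a
    BH-adjusted column is included but not used for filtering.
    """
    if matrix.layer_tag != "lognorm":
        raise ValidationError("find_markers expects lognorm layer")
    labels = labels.reindex(matrix.cell_ids)
    mask_in = (labels == cluster).values
    if not mask_in.any():
        raise ValidationError(f"unknown cluster label {cluster!r}")
    mask_out = ~mask_in
    if mask_in.sum() < 3 or mask_out.sum() < 3:
        raise ValidationError("need >= 3 cells in the cluster and its complement")

    dense = matrix.dense()
    x_in, x_out = dense[:, mask_in], dense[:, mask_out]
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log_fc = np.log(mean_in + 1) - np.log(mean_out + 1)
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)

    stats = np.zeros(matrix.n_genes)
    pvals = np.ones(matrix.n_genes)
    for g in range(matrix.n_genes):
        stats[g], pvals[g] = wilcoxon_rank_sum(x_in[g], x_out[g])

    adj = _benjamini_hochberg(pvals)
    table = pd.DataFrame(
        {
            "cluster": cluster,
            "gene": matrix.gene_ids,
            "log_fc": log_fc,
            "p_value": pvals,
            "p_adj": adj,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "statistic": stats,
        }
    )
    keep = (table["log_fc"] > min_logfc) & (table["p_value"] < max_p)
    return (
        table[keep]
        .sort_values(["p_value", "gene"], kind="stable")
        .reset_index(drop=True)
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def find_all_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    min_logfc: float = 0.25,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """find_markers for every label value, concatenated."""
    tables = []
    for cluster in sorted(pd.Series(labels).unique()):
        tables.append(find_markers(matrix, labels, cluster, min_logfc, max_p))
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


# ---------------------------------------------------------------------------
# Proportions and group comparison
# ---------------------------------------------------------------------------


def subgroup_proportions(
    cell_annotation: pd.DataFrame, level: str = "cell_type"
) -> pd.DataFrame:
    """Per-patient label fractions at the chosen level (rows sum to 1)."""
    if level not in cell_annotation.columns:
        raise ValidationError(f"no column {level!r} in cell annotation")
    counts = (
        cell_annotation.groupby(["patient_id", level], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"excluding patients with zero cells: {list(counts.index[empty])}")
        counts = counts[~empty]
        totals = totals[~empty]
    return counts.div(totals, axis=0)


@dataclass
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    decision_trail: list[str] = field(default_factory=list)


def compare_groups(
    x,
    y,
    paired: bool = False,
    alpha_normality: float = 0.05,
) -> GroupComparisonResult:
    """Normality-driven two-group test selection.

    Unpaired: Shapiro-Wilk per group; both normal -> F-test of
    variance homogeneity -> Student or Welch t; otherwise
    Mann-Whitney. Paired: Shapiro-Wilk on differences; normal ->
    paired t, otherwise Wilcoxon signed-rank.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise DegenerateInputError("need >= 3 observations per group")
    trail: list[str] = []

    if paired:
        if len(x) != len(y):
            raise DegenerateInputError("paired comparison needs equal lengths")
        d = x - y
        if np.allclose(d, d[0]):
            if d[0] == 0:
                raise DegenerateInputError("all paired differences are zero")
            raise DegenerateInputError("constant nonzero paired differences")
        p_norm = scipy.stats.shapiro(d).pvalue
        trail.append(f"shapiro(differences) p={p_norm:.4g}")
        if p_norm > alpha_normality:
            trail.append("differences normal -> paired t-test")
            res = scipy.stats.ttest_rel(x, y)
            return GroupComparisonResult("paired_t", float(res.statistic), float(res.pvalue), trail)
        trail.append("differences non-normal -> Wilcoxon signed-rank")
        res = scipy.stats.wilcoxon(x, y)
        return GroupComparisonResult(
            "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), trail
        )

    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        if x[0] == y[0]:
            raise DegenerateInputError("both groups constant and equal")
        raise DegenerateInputError("both groups constant; no test defined")

    def _normal(v: np.ndarray, label: str) -> bool:
        if np.allclose(v, v[0]):
            trail.append(f"{label} constant -> treated as non-normal")
            return False
        p = scipy.stats.shapiro(v).pvalue
        trail.append(f"shapiro({label}) p={p:.4g}")
        return p > alpha_normality

    if _normal(x, "x") and _normal(y, "y"):
        f = np.var(x, ddof=1) / np.var(y, ddof=1)
        dfx, dfy = len(x) - 1, len(y) - 1
        p_f = 2 * min(
            scipy.stats.f.cdf(f, dfx, dfy), scipy.stats.f.sf(f, dfx, dfy)
        )
        trail.append(f"F-test variance homogeneity p={p_f:.4g}")
        if p_f > alpha_normality:
            trail.append("variances homogeneous -> Student t")
            res = scipy.stats.ttest_ind(x, y, equal_var=True)
            return GroupComparisonResult(
                "student_t", float(res.statistic), float(res.pvalue), trail
            )
        trail.append("variances heterogeneous -> Welch t")
        res = scipy.stats.ttest_ind(x, y, equal_var=False)
        return GroupComparisonResult("welch_t", float(res.statistic), float(res.pvalue), trail)

    trail.append("non-normal -> Mann-Whitney")
    z, p = wilcoxon_rank_sum(x, y)
    return GroupComparisonResult("mann_whitney", float(z), float(p), trail)
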