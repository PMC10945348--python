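import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats
from itertools import combinations
from math import comb
from sklearn.metrics import adjusted_rand_score

from immunosig.errors import DegenerateInputError, ValidationError
from immunosig.io_formats import ExpressionMatrix
from immunosig.sc_core import (
    cluster_cells,
    compare_groups,
    find_markers,
    normalize_lognorm,
    qc_filter,
    subgroup_proportions,
    wilcoxon_rank_sum,
)
from immunosig.synthetic_data import true_marker_genes


def _matrix(dense, layer_tag="counts"):
    dense = np.asarray(dense)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(dense.shape[0])],
        cell_ids=[f"c{j}" for j in range(dense.shape[1])],
        counts=sp.csr_matrix(dense),
        layer_tag=layer_tag,
    )


def _annotation(matrix, mito_genes=()):
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "chromosome": ["1"] * matrix.n_genes,
            "start": np.arange(1, matrix.n_genes + 1),
            "is_mito": [g in mito_genes for g in matrix.gene_ids],
        }
    )


class TestQcFilter:
    def test_detected_gene_bounds(self):
        rng = np.random.default_rng(0)
        n_genes = 7000
        dense = np.zeros((n_genes, 3), dtype=int)
        for j, n_detected in enumerate([150, 500, 6500]):
            idx = rng.choice(n_genes, n_detected, replace=False)
            dense[idx, j] = 1
        m = _matrix(dense)
        out, cells, report = qc_filter(m, _annotation(m), min_cells_per_gene=1)
        assert out.cell_ids == ["c1"]
        assert report.removed_low_genes == 1 and report.removed_high_genes == 1

    def test_mito_threshold(self):
        # cell c0: 12/100 mito counts -> removed; c1: 5/100 -> kept
        dense = np.zeros((300, 2), dtype=int)
        dense[:250, 0] = 1  # fills detected-gene floor
        dense[:250, 1] = 1
        dense[299, 0] = 34  # mito gene; 34/284 = 0.1197
        dense[299, 1] = 10  # 10/260 = 0.038
        m = _matrix(dense)
        ann = _annotation(m, mito_genes={"g299"})
        out, cells, report = qc_filter(m, ann, min_genes=100, min_cells_per_gene=1)
        assert out.cell_ids == ["c1"]
        assert report.removed_mito == 1

    def test_gene_min_cell_boundary(self):
        dense = np.zeros((500, 4), dtype=int)
        dense[:400] = 1  # keeps cells above min_genes
        dense[400, :2] = 1  # gene in 2 cells -> removed
        dense[401, :3] = 1  # gene in 3 cells -> kept
        m = _matrix(dense)
        out, _, _ = qc_filter(m, _annotation(m), min_genes=100)
        assert "g400" not in out.gene_ids
        assert "g401" in out.gene_ids

    def test_idempotent(self, small_sc_data):
        matrix, _, gene_ann = small_sc_data
        once, _, _ = qc_filter(matrix, gene_ann, min_genes=10)
        twice, _, _ = qc_filter(once, gene_ann, min_genes=10)
        assert once == twice

    def test_all_cells_removed_is_error(self):
        dense = np.ones((10, 3), dtype=int)
        m = _matrix(dense)
        with pytest.raises(ValidationError):
            qc_filter(m, _annotation(m), min_genes=200)


class TestNormalize:
    def test_closed_form_single_gene(self):
        m = _matrix([[100], [0]])
        out = normalize_lognorm(m)
        assert out.dense()[0, 0] == pytest.approx(np.log(1 + 1e4), abs=1e-6)
        assert out.layer_tag == "lognorm"

    def test_all_zero_gene_stays_zero(self):
        m = _matrix([[1, 2], [0, 0]])
        out = normalize_lognorm(m)
        assert (out.dense()[1] == 0).all()

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(3, size=(20, 1)) + 1
        a = normalize_lognorm(_matrix(base))
        b = normalize_lognorm(_matrix(base * 2))
        np.testing.assert_allclose(a.dense(), b.dense(), atol=1e-12)

    def test_zero_total_cell_is_error(self):
        with pytest.raises(ValidationError):
            normalize_lognorm(_matrix([[1, 0], [1, 0]]))


class TestClusterCells:
    def _blobs(self, delta=4.0, n=60, n_genes=40, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n_genes, n))
        b = rng.normal(0, 1, size=(n_genes, n))
        b[: n_genes // 2] += delta
        dense = np.abs(np.concatenate([a, b], axis=1))
        m = _matrix(dense, layer_tag="lognorm")
        truth = np.array([0] * n + [1] * n)
        return m, truth

    def test_two_blobs_recovered(self):
        m, truth = self._blobs()
        labels = cluster_cells(m, n_pcs=10, n_hvg=40, resolution=0.5, seed=0)
        assert labels.nunique() == 2
        assert adjusted_rand_score(truth, labels.values) > 0.95

    def test_identical_cells_single_cluster(self):
        dense = np.tile(np.arange(30, dtype=float).reshape(-1, 1), (1, 25))
        m = _matrix(dense, layer_tag="lognorm")
        labels = cluster_cells(m, n_pcs=5, n_hvg=30, seed=0)
        assert labels.nunique() == 1

    def test_seeded_determinism(self):
        m, _ = self._blobs(delta=1.5, seed=3)
        a = cluster_cells(m, n_pcs=10, n_hvg=40, seed=7)
        b = cluster_cells(m, n_pcs=10, n_hvg=40, seed=7)
        assert a.equals(b)

    def test_n_pcs_too_large(self):
        m, _ = self._blobs(n=10, n_genes=8)
        with pytest.raises(ValidationError):
            cluster_cells(m, n_pcs=50)


def exhaustive_ranksum_p(x, y):
    """Independent oracle: enumerate every group assignment of the pooled
    values and compute the two-sided doubled-tail probability of the
    observed rank sum."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    total = comb(len(pooled), n1)
    lo = sum(
        1 for c in combinations(range(len(pooled)), n1)
        if ranks[list(c)].sum() <= w_obs + 1e-9
    )
    hi = sum(
        1 for c in combinations(range(len(pooled)), n1)
        if ranks[list(c)].sum() >= w_obs - 1e-9
    )
    return min(1.0, 2.0 * min(lo / total, hi / total))


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_fully_separated_small_groups(self):
        # all 20 assignments enumerable; observed rank sum is the minimum
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, size=2)
        # integer draws force ties with high probability
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exhaustive_ranksum_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_asymptotic_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = np.round(rng.normal(0.5, 1, size=25), 1)
        _, p = wilcoxon_rank_sum(x, y)
        expected = scipy.stats.mannwhitneyu(
            x, y, method="asymptotic", use_continuity=False
        ).pvalue
        assert p == pytest.approx(expected, rel=1e-9)


class TestFindMarkers:
    def test_identical_gene_excluded(self):
        dense = np.ones((2, 10))
        dense[1, :5] = 3.0  # real marker so the call returns rows
        m = _matrix(dense, layer_tag="lognorm")
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=m.cell_ids)
        table = find_markers(m, labels, "a")
        assert "g0" not in set(table["gene"])

    def test_logfc_definition(self):
        rng = np.random.default_rng(0)
        dense = np.abs(rng.normal(1, 0.3, size=(3, 12)))
        dense[0, :6] += 2.0
        m = _matrix(dense, layer_tag="lognorm")
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.cell_ids)
        table = find_markers(m, labels, "a", min_logfc=-10, max_p=1.1)
        row = table[table["gene"] == "g0"].iloc[0]
        expected = np.log(np.expm1(dense[0, :6]).mean() + 1) - np.log(
            np.expm1(dense[0, 6:]).mean() + 1
        )
        assert row["log_fc"] == pytest.approx(expected, abs=1e-12)

    def test_planted_marker_recall(self, small_lognorm, small_sc_config):
        lognorm, labels, _ = small_lognorm
        table = find_markers(lognorm, labels["subgroup"], "CD8T")
        truth = set(true_marker_genes(small_sc_config, "CD8T"))
        truth &= set(lognorm.gene_ids)
        recall = len(truth & set(table["gene"])) / len(truth)
        assert recall >= 0.9

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(2)
        dense = np.abs(rng.normal(1, 0.5, size=(5, 20)))
        m = _matrix(dense, layer_tag="lognorm")
        labels = pd.Series(rng.permutation(["a"] * 10 + ["b"] * 10), index=m.cell_ids)
        perm = rng.permutation(m.n_cells)
        m2 = ExpressionMatrix(
            gene_ids=m.gene_ids,
            cell_ids=[m.cell_ids[i] for i in perm],
            counts=m.counts[:, perm],
            layer_tag="lognorm",
        )
        t1 = find_markers(m, labels, "a", min_logfc=-10, max_p=1.1)
        t2 = find_markers(m2, labels, "a", min_logfc=-10, max_p=1.1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_cluster(self):
        m = _matrix(np.ones((2, 6)), layer_tag="lognorm")
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=m.cell_ids)
        with pytest.raises(ValidationError):
            find_markers(m, labels, "zzz")


class TestProportions:
    def test_simple_fraction(self):
        ann = pd.DataFrame(
            {
                "patient_id": ["p1"] * 10,
                "cell_type": ["T"] * 4 + ["B"] * 6,
            }
        )
        out = subgroup_proportions(ann, level="cell_type")
        assert out.loc["p1", "T"] == pytest.approx(0.4)

    def test_rows_sum_to_one(self, small_sc_data):
        _, cell_ann, _ = small_sc_data
        out = subgroup_proportions(cell_ann, level="subgroup")
        np.testing.assert_allclose(out.sum(axis=1), 1.0)

    def test_zero_fraction_subgroup_is_zero(self, small_sc_data):
        _, cell_ann, _ = small_sc_data
        out = subgroup_proportions(cell_ann, level="subgroup")
        pd_pre_patients = cell_ann.loc[
            cell_ann["group"] == "PD-pre", "patient_id"
        ].unique()
        assert (out.loc[pd_pre_patients, "B_CD74"] == 0).all()


class TestCompareGroups:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_groups(x, x.copy())
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_normal_path_strong_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        res = compare_groups(x, y)
        assert res.test_name in ("student_t", "welch_t")
        assert res.p_value < 1e-6
        assert any("shapiro" in step for step in res.decision_trail)

    def test_cauchy_takes_mann_whitney_branch(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = compare_groups(rng.standard_cauchy(30), rng.standard_cauchy(30))
            hits += res.test_name == "mann_whitney"
        assert hits >= 90

    def test_swap_flips_statistic_preserves_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        a = compare_groups(x, y)
        b = compare_groups(y, x)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-9)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            res = compare_groups(rng.normal(size=10), rng.normal(size=12))
            assert 0 < res.p_value <= 1

    def test_paired_branches(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 25)
        res = compare_groups(x, x + rng.normal(0.5, 0.1, 25), paired=True)
        assert res.test_name in ("paired_t", "wilcoxon_signed_rank")

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_too_small_groups(self):
        with pytest.raises(DegenerateInputError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
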