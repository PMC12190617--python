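"""Single-cell QC, normalization, Wilcoxon DE and the candidate screen."""

import itertools

import numpy as np
import pytest
from scipy import sparse, stats

from pqtlmr.sc import (
    SparseCountMatrix,
    candidate_screen,
    normalize,
    qc_filter,
    read_mtx,
    wilcoxon_de,
    write_mtx,
)
from pqtlmr.synthetic import simulate_counts


def matrix_from_dense(arr):
    arr = np.asarray(arr)
    return SparseCountMatrix(
        [f"g{i}" for i in range(arr.shape[0])],
        [f"c{j}" for j in range(arr.shape[1])],
        sparse.csr_matrix(arr),
    )


class TestQC:
    def test_clean_matrix_unchanged(self):
        m = matrix_from_dense(np.ones((4, 5), dtype=int))
        out, rep = qc_filter(m, min_cells=3, min_features=2)
        assert out.shape == (4, 5)
        assert rep["genes_after"] == rep["genes_before"]

    def test_toy_filter_trace(self):
        """6 genes x 5 cells; one gene seen in 2 cells and one cell with 1
        detected gene, at toy thresholds 3 cells / 2 features -> 5 x 4."""
        a = np.ones((6, 5), dtype=int)
        a[0, :] = 0
        a[0, :2] = 1          # gene 0 expressed in only 2 cells
        a[1:, 4] = 0          # cell 4 detects only gene 0 -> 0 after gene drop
        m = matrix_from_dense(a)
        out, rep = qc_filter(m, min_cells=3, min_features=2)
        assert out.shape == (5, 4)
        assert rep == {"genes_before": 6, "cells_before": 5,
                       "genes_after": 5, "cells_after": 4}

    def test_idempotent(self):
        rng = np.random.default_rng(20)
        m = matrix_from_dense(rng.poisson(0.5, (50, 40)))
        once, _ = qc_filter(m, min_cells=3, min_features=5)
        twice, _ = qc_filter(once, min_cells=3, min_features=5)
        assert once.genes == twice.genes and once.cells == twice.cells
        assert (once.x != twice.x).nnz == 0

    def test_monotone_dimensions(self):
        rng = np.random.default_rng(21)
        m = matrix_from_dense(rng.poisson(0.3, (80, 60)))
        out, rep = qc_filter(m, min_cells=3, min_features=5)
        assert rep["genes_after"] <= rep["genes_before"]
        assert rep["cells_after"] <= rep["cells_before"]


class TestNormalize:
    def test_known_value(self):
        # cell total 10,000 and count 1 -> ln 2
        col = np.zeros((2, 1), dtype=int)
        col[0, 0] = 1
        col[1, 0] = 9999
        m = matrix_from_dense(col)
        out = normalize(m)
        assert out.x[0, 0] == pytest.approx(np.log(2))

    def test_depth_invariance(self):
        rng = np.random.default_rng(22)
        a = rng.poisson(2.0, (10, 8)) + 1
        n1 = normalize(matrix_from_dense(a))
        n2 = normalize(matrix_from_dense(2 * a))
        np.testing.assert_allclose(n1.x.toarray(), n2.x.toarray(), rtol=1e-12)

    def test_all_zero_gene_stays_zero(self):
        a = np.ones((3, 4), dtype=int)
        a[1] = 0
        out = normalize(matrix_from_dense(a))
        assert out.x[1].nnz == 0


class TestMTXRoundtrip:
    def test_roundtrip(self, tmp_path):
        m, _ = simulate_counts(15, {"T": 10}, seed=23)
        write_mtx(m, tmp_path / "mtx")
        back = read_mtx(tmp_path / "mtx")
        assert back.genes == m.genes and back.cells == m.cells
        assert (back.x != m.x).nnz == 0


def _expr(case_vals, ctrl_vals):
    """Normalized matrix with one gene and fixed per-cell values."""
    vals = np.concatenate([case_vals, ctrl_vals])[None, :]
    m = SparseCountMatrix(
        ["g0"], [f"c{j}" for j in range(vals.shape[1])], sparse.csr_matrix(vals))
    mask_a = np.arange(vals.shape[1]) < len(case_vals)
    return m, mask_a, ~mask_a


class TestWilcoxon:
    def test_identical_groups(self):
        m, a, b = _expr(np.ones(5), np.ones(5))
        [r] = wilcoxon_de(m, a, b)
        assert r.p == 1.0
        assert r.log2fc == pytest.approx(0.0, abs=1e-6)

    def test_exact_permutation_oracle_5v5(self):
        """The rank-sum p on 5 vs 5 distinct values equals brute-force
        enumeration over all C(10,5) group assignments (exact test)."""
        x = np.array([1.3, 2.1, 0.2, 3.3, 4.1])
        y = np.array([0.1, 0.5, 2.5, 0.9, 1.1])
        m, a, b = _expr(x, y)
        [r] = wilcoxon_de(m, a, b)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:5].sum()
        null = [
            ranks[list(c)].sum() for c in itertools.combinations(range(10), 5)
        ]
        null = np.array(null)
        mu = null.mean()
        p_exact = np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-12)
        exact = stats.mannwhitneyu(x, y, method="exact").pvalue
        assert exact == pytest.approx(p_exact, rel=1e-12)
        # asymptotic result used by the screen agrees with the exact law
        assert r.p == pytest.approx(p_exact, abs=0.1)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(24)
        x = rng.lognormal(0, 1, 30)
        y = rng.lognormal(0.5, 1, 30)
        m1, a, b = _expr(x, y)
        m2, _, _ = _expr(x**3, y**3)
        [r1] = wilcoxon_de(m1, a, b)
        [r2] = wilcoxon_de(m2, a, b)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_bonferroni_bounds(self):
        rng = np.random.default_rng(25)
        m = matrix_from_dense(rng.poisson(1.0, (20, 40)))
        expr = normalize(m)
        mask = np.arange(40) < 20
        for r in wilcoxon_de(expr, mask, ~mask, n_comparisons=3):
            assert r.p <= r.p_bonf <= 1.0

    def test_planted_shift_detected(self):
        m, ann = simulate_counts(
            40, {"T": 200}, de_genes={"G0003": ("T", "case", 2.0)},
            dispersion=0.3, depth=3000, seed=26)
        mq, _ = qc_filter(m, 3, 5)
        expr = normalize(mq)
        mask_case = (ann.set_index("barcode").loc[expr.cells, "condition"] == "case").to_numpy()
        [r] = wilcoxon_de(expr, mask_case, ~mask_case, genes=["G0003"])
        assert r.p_bonf < 0.05
        assert 1.5 <= r.log2fc <= 2.5

    def test_small_group_flagged_unreliable(self):
        m, a, b = _expr(np.array([1.0, 2.0]), np.ones(5))
        [r] = wilcoxon_de(m, a, b)
        assert not r.reliable


@pytest.fixture(scope="module")
def screened():
    m, ann = simulate_counts(
        30,
        {"T": 300, "KC": 300},
        de_genes={"G0007": ("T", "case", 2.5)},
        dispersion=0.3,
        depth=3000,
        seed=27,
    )
    mq, _ = qc_filter(m, 3, 5)
    expr = normalize(mq)
    ann = ann[ann["barcode"].isin(expr.cells)]
    tab = candidate_screen(expr, ann, ["G0007", "G0001", "ABSENT"], raw=mq)
    return tab.set_index("gene")


class TestCandidateScreen:
    def test_planted_celltype_specific_flag(self, screened):
        assert "T:case" in screened.loc["G0007", "specific"]

    def test_flat_gene_not_flagged(self, screened):
        assert screened.loc["G0001", "specific"] == ""

    def test_absent_candidate_row(self, screened):
        row = screened.loc["ABSENT"]
        assert not row["detected_case"] and not row["detected_control"]
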