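"""Single-cell QC, covariate regression, and the variance-ratio bound."""

import numpy as np
import pandas as pd
import pytest

from paretotasks.heterogeneity import (
    exclude_by_markers,
    qc_filter,
    regress_covariates,
    shuffled_reference_control,
    variance_explained_ratio,
)


def _counts(seed=0, n=50, g=40):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.poisson(5.0, size=(n, g)),
                        index=[f"c{i:03d}" for i in range(n)],
                        columns=[f"g{i:03d}" for i in range(g)])


class TestQcFilter:
    def test_cell_gates(self):
        # cells with 5, 20, and 35 detectable genes against gates [10, 30]
        rows = np.zeros((10, 40), dtype=int)
        rows[0, :5] = 1
        rows[1:9, :20] = 1
        rows[9, :35] = 1
        counts = pd.DataFrame(rows, index=[f"c{i:03d}" for i in range(10)],
                              columns=[f"g{i:03d}" for i in range(40)])
        out = qc_filter(counts, min_gene_cell_fraction=0.0,
                        min_genes=10, max_genes=30)
        assert "c000" not in out.index  # too few detectable genes
        assert "c009" not in out.index  # too many
        assert len(out) == 8

    def test_rare_gene_removed(self):
        counts = _counts()
        counts["rare"] = 0
        counts.loc["c000", "rare"] = 3  # detected in 2% of cells
        out = qc_filter(counts, min_gene_cell_fraction=0.05,
                        min_genes=1, max_genes=10_000)
        assert "rare" not in out.columns

    def test_idempotent(self):
        counts = _counts(1)
        once = qc_filter(counts, 0.05, 10, 45)
        twice = qc_filter(once, 0.05, 10, 45)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_rejected(self):
        counts = _counts(2)
        with pytest.raises(ValueError):
            qc_filter(counts, min_gene_cell_fraction=0.0,
                      min_genes=10_000, max_genes=20_000)


class TestMarkerExclusion:
    def test_planted_marker_cells_excluded(self):
        counts = _counts(3)
        counts["PTPRC"] = 0
        counts.loc[counts.index[:10], "PTPRC"] = 7
        out = exclude_by_markers(counts)
        assert len(out) == 40
        assert not set(counts.index[:10]) & set(out.index)

    def test_no_marker_expression_identity(self):
        counts = _counts(4)
        counts["PTPRC"] = 0
        assert len(exclude_by_markers(counts)) == len(counts)

    def test_missing_markers_skipped(self):
        counts = _counts(5)  # no marker genes at all
        assert len(exclude_by_markers(counts)) == len(counts)


class TestRegression:
    def _cov(self, n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "total_count": rng.uniform(500, 1500, size=n),
            "mito_fraction": rng.uniform(0, 0.2, size=n),
            "tumor_id": ["T1"] * (n // 2) + ["T2"] * (n - n // 2),
        }, index=[f"c{i:03d}" for i in range(n)])

    def test_gene_equal_to_covariate_residual_zero(self):
        cov = self._cov(30, 6)
        expr = pd.DataFrame({"g": cov["total_count"]}, index=cov.index)
        res = regress_covariates(expr, cov)
        np.testing.assert_allclose(res["g"], 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        cov = self._cov(40, 7)
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(40, 5)), index=cov.index)
        res = regress_covariates(expr, cov)
        for col in ("total_count", "mito_fraction"):
            dots = res.T @ cov[col].to_numpy()
            np.testing.assert_allclose(dots, 0.0, atol=1e-6)
        assert np.abs(res.mean(axis=0)).max() < 1e-8

    def test_matches_normal_equations_oracle(self):
        cov = self._cov(25, 8)
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(25, 3)), index=cov.index)
        res = regress_covariates(expr, cov)
        design = np.column_stack([
            np.ones(25),
            cov["total_count"], cov["mito_fraction"],
            (cov["tumor_id"] == "T2").astype(float),
        ])
        beta = np.linalg.solve(design.T @ design, design.T @ expr.to_numpy())
        oracle = expr.to_numpy() - design @ beta
        np.testing.assert_allclose(res.to_numpy(), oracle, atol=1e-8)


class TestVarianceRatio:
    def _cells_in_span(self, loadings, n=40, seed=9):
        rng = np.random.default_rng(9)
        coeffs = rng.normal(size=(n, loadings.shape[1]))
        return coeffs @ loadings.T

    def test_cells_in_reference_span_ratio_one(self):
        rng = np.random.default_rng(10)
        g = 30
        ref, _ = np.linalg.qr(rng.normal(size=(g, 3)))
        cells = pd.DataFrame(self._cells_in_span(ref),
                             columns=[f"g{i}" for i in range(g)])
        loadings = pd.DataFrame(ref, index=cells.columns)
        tumor_ids = pd.Series("T1", index=cells.index)
        table = variance_explained_ratio(cells, tumor_ids, loadings, m=3)
        assert table.loc["T1", "ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_cells_ratio_zero(self):
        rng = np.random.default_rng(11)
        g = 30
        q, _ = np.linalg.qr(rng.normal(size=(g, 6)))
        ref, comp = q[:, :3], q[:, 3:]
        cells = pd.DataFrame(self._cells_in_span(comp),
                             columns=[f"g{i}" for i in range(g)])
        loadings = pd.DataFrame(ref, index=cells.columns)
        table = variance_explained_ratio(
            cells, pd.Series("T1", index=cells.index), loadings, m=3)
        assert table.loc["T1", "ratio"] == pytest.approx(0.0, abs=1e-10)

    def test_ratio_bounded_by_one(self):
        rng = np.random.default_rng(12)
        cells = pd.DataFrame(rng.normal(size=(60, 25)),
                             columns=[f"g{i}" for i in range(25)])
        ref, _ = np.linalg.qr(rng.normal(size=(25, 5)))
        loadings = pd.DataFrame(ref, index=cells.columns)
        ids = pd.Series(["T1"] * 30 + ["T2"] * 30, index=cells.index)
        table = variance_explained_ratio(cells, ids, loadings, m=5)
        assert (table["ratio"] <= 1.0 + 1e-6).all()
        assert (table["ratio"] >= 0.0).all()

    def test_small_tumors_excluded(self):
        rng = np.random.default_rng(13)
        cells = pd.DataFrame(rng.normal(size=(12, 10)),
                             columns=[f"g{i}" for i in range(10)])
        ids = pd.Series(["T1"] * 10 + ["T2"] * 2, index=cells.index)
        ref, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        loadings = pd.DataFrame(ref, index=cells.columns)
        table = variance_explained_ratio(cells, ids, loadings, m=3)
        assert list(table.index) == ["T1"]


class TestShuffledControl:
    def test_permutation_preserves_per_gene_variance(self):
        rng = np.random.default_rng(14)
        tumors = pd.DataFrame(rng.normal(size=(50, 12)),
                              columns=[f"g{i}" for i in range(12)])
        x = tumors.to_numpy()
        shuffled = np.empty_like(x)
        for j in range(x.shape[1]):
            shuffled[:, j] = x[rng.permutation(50), j]
        np.testing.assert_allclose(shuffled.var(axis=0), x.var(axis=0))

    def test_aligned_cells_beat_control(self):
        rng = np.random.default_rng(15)
        g, n_tumors, cells_per = 40, 6, 25
        tumors = pd.DataFrame(rng.normal(size=(60, g)),
                              columns=[f"g{i}" for i in range(g)])
        centered = tumors.to_numpy() - tumors.to_numpy().mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        span = vt[:3].T
        cells, ids = [], []
        for t in range(n_tumors):
            coeffs = rng.normal(size=(cells_per, 3))
            cells.append(coeffs @ span.T + rng.normal(size=(cells_per, g)) * 0.05)
            ids += [f"T{t}"] * cells_per
        cells = pd.DataFrame(np.vstack(cells), columns=tumors.columns)
        ids = pd.Series(ids, index=cells.index)
        table, p, control_mean = shuffled_reference_control(
            tumors, cells, ids, m=3, n_reps=5, seed=16)
        assert table["ratio"].mean() > control_mean
        assert p < 0.01


class TestPcCountRobustness:
    def test_fully_aligned_cells_flat_in_m(self):
        from paretotasks.heterogeneity import pc_count_robustness

        rng = np.random.default_rng(17)
        g = 30
        tumors = pd.DataFrame(rng.normal(size=(40, g)),
                              columns=[f"g{i}" for i in range(g)])
        centered = tumors.to_numpy() - tumors.to_numpy().mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        span = vt[:2].T
        cells = pd.DataFrame(rng.normal(size=(60, 2)) @ span.T,
                             columns=tumors.columns)
        ids = pd.Series(["T1"] * 30 + ["T2"] * 30, index=cells.index)
        table = pc_count_robustness(cells, ids, tumors, [2])
        assert table.loc[2, "mean_ratio"] == pytest.approx(1.0, abs=1e-8)
        # a larger reference basis still contains the cells' span
        table5 = pc_count_robustness(cells, ids, tumors, [5])
        assert table5.loc[5, "mean_ratio"] >= 0.99
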