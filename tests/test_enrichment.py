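"""Distance bins, enrichment statistics, FDR, and the peak rule."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from paretotasks.enrichment import (
    bh_fdr,
    bin_by_distance,
    enrichment_table,
    first_bin_size,
    pathway_scores,
    peak_in_first_bin,
)
from paretotasks.enrichment import test_continuous as mwu_first_bin
from paretotasks.enrichment import test_discrete as hypergeom_first_bin
from paretotasks.io import GeneSetCollection
from paretotasks.preprocess import ExpressionMatrix


def _binning(n, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame(rng.standard_normal((n, 2)),
                          index=[f"s{i:04d}" for i in range(n)])
    return bin_by_distance(scores, np.zeros(2), **kwargs)


class TestFirstBinRule:
    def test_fifty_tumors_for_1000(self):
        assert first_bin_size(1000) == 50

    def test_five_percent_of_pooled_cohort(self):
        # 3180 pooled tumors: the 5% rule takes over, giving 159
        assert first_bin_size(3180) == 159

    def test_fifty_is_twenty_percent_of_250(self):
        b = first_bin_size(250)
        assert b == 50
        assert b / 250 == pytest.approx(0.20)

    def test_binning_partitions_samples(self):
        binning = _binning(300, n_bins=5)
        assert len(binning.first_bin) == first_bin_size(300)
        counts = binning.bin_index.value_counts()
        assert counts.sum() == 300
        assert set(counts.index) == {0, 1, 2, 3, 4}

    def test_distances_sorted_ascending(self):
        binning = _binning(200)
        d = binning.distances.to_numpy()
        assert (np.diff(d) >= 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            _binning(20, base_count=50)


class TestContinuous:
    def test_perfect_ordering_significant(self):
        binning = _binning(500, seed=1)
        feature = -binning.distances  # closest tumors take the highest values
        _, p, direction = mwu_first_bin(feature, binning)
        assert p < 1e-6
        assert direction > 0

    def test_constant_feature_p_one(self):
        binning = _binning(100, seed=2)
        _, p, _ = mwu_first_bin(pd.Series(1.0, index=binning.sample_ids), binning)
        assert p == 1.0

    def test_permuted_feature_calibrated(self):
        binning = _binning(150, seed=3)
        rng = np.random.default_rng(3)
        pvals = []
        base = rng.standard_normal(150)
        for _ in range(300):
            f = pd.Series(rng.permutation(base), index=binning.sample_ids)
            pvals.append(mwu_first_bin(f, binning)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestDiscrete:
    def test_exact_hypergeometric_example(self):
        # 20 samples, 10 positives, bin of 5, all 5 positive:
        # p = C(10,5) C(10,0) / C(20,5) = 252 / 15504
        ids = [f"s{i:02d}" for i in range(20)]
        scores = pd.DataFrame(np.arange(20, dtype=float)[:, None], index=ids)
        binning = bin_by_distance(scores, np.array([0.0]), base_count=5,
                                  min_fraction=0.01, n_bins=2)
        labels = pd.Series([1] * 5 + [0] * 10 + [1] * 5, index=ids)
        fold, p = hypergeom_first_bin(labels, binning)
        assert p == pytest.approx(252 / 15504)
        assert fold == pytest.approx((5 / 5) / (10 / 20))

    def test_all_positive_degenerate(self):
        binning = _binning(100, seed=4)
        labels = pd.Series(1, index=binning.sample_ids)
        fold, p = hypergeom_first_bin(labels, binning)
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_matches_brute_force_tail_sum(self):
        from scipy.special import comb

        ids = [f"s{i:02d}" for i in range(25)]
        scores = pd.DataFrame(np.arange(25, dtype=float)[:, None], index=ids)
        binning = bin_by_distance(scores, np.array([0.0]), base_count=6,
                                  min_fraction=0.01, n_bins=2)
        rng = np.random.default_rng(5)
        labels = pd.Series(rng.integers(0, 2, size=25), index=ids)
        big_k = int(labels.sum())
        x = int(labels[binning.first_bin].sum())
        brute = sum(
            comb(big_k, j) * comb(25 - big_k, 6 - j) / comb(25, 6)
            for j in range(x, min(big_k, 6) + 1)
        )
        _, p = hypergeom_first_bin(labels, binning)
        assert p == pytest.approx(brute, rel=1e-9)


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_computed(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_order_equivariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


class TestPeakRule:
    def _feature(self, binning, per_bin_values):
        return pd.Series(binning.bin_index.map(dict(enumerate(per_bin_values))),
                         index=binning.sample_ids, dtype=float)

    def test_monotone_decreasing_peaks(self):
        binning = _binning(250, seed=7)
        assert peak_in_first_bin(self._feature(binning, [5, 4, 3, 2, 1]), binning)

    def test_interior_maximum_fails(self):
        binning = _binning(250, seed=8)
        assert not peak_in_first_bin(self._feature(binning, [1, 2, 5, 2, 1]), binning)

    def test_tie_is_conservative(self):
        binning = _binning(250, seed=9)
        assert not peak_in_first_bin(self._feature(binning, [5, 5, 1, 1, 1]), binning)


class TestPathwayScores:
    def _expr(self, seed=10, n=6, g=8):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(n, g)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(g)],
        ))

    def test_singleton_set_copies_gene(self):
        expr = self._expr()
        out = pathway_scores(expr, GeneSetCollection({"S": ["g3"]}))
        np.testing.assert_allclose(out["S"], expr.values["g3"])

    def test_matches_row_mean_oracle(self):
        expr = self._expr()
        sets = GeneSetCollection({"S": ["g1", "g4", "g6"]})
        out = pathway_scores(expr, sets)
        np.testing.assert_allclose(
            out["S"], expr.values[["g1", "g4", "g6"]].mean(axis=1))

    def test_absent_set_excluded(self):
        expr = self._expr()
        out = pathway_scores(expr, GeneSetCollection({"S": ["nope"]}))
        assert "S" not in out.columns


class TestEnrichmentTable:
    def test_planted_feature_reported_at_right_archetype(self):
        rng = np.random.default_rng(11)
        n = 300
        ids = [f"s{i:04d}" for i in range(n)]
        scores = pd.DataFrame(rng.standard_normal((n, 2)), index=ids)
        arch0, arch1 = np.array([3.0, 0.0]), np.array([-3.0, 0.0])
        binnings = [
            bin_by_distance(scores, arch0, archetype_id=0),
            bin_by_distance(scores, arch1, archetype_id=1),
        ]
        # feature rising toward archetype 0 only
        feature = pd.DataFrame(
            {"f": -np.linalg.norm(scores.to_numpy() - arch0, axis=1)}, index=ids)
        table = enrichment_table(feature, binnings, "continuous", fdr_q=0.10)
        reported = table[table["reported"]]
        assert list(reported["archetype"]) == [0]


class TestLeaveOneOut:
    def _planted(self, diffuse, seed=20):
        from paretotasks.synthetic import make_truth, generate_tumors
        from paretotasks.preprocess import center_genes

        truth = make_truth(n_samples=200, n_archetypes=3, n_genes=400,
                           block_size=110, block_effect=2.0,
                           dirichlet_concentration=0.3, noise_sd=0.1,
                           seed=seed)
        if not diffuse:
            # archetype 0 is supported only by its own block: outside it,
            # its profile is the midpoint of the other two archetypes, so
            # deleting the block collapses its vertex onto their edge
            truth.archetypes[:, :] = 0.0
            for a in range(3):
                truth.archetypes[a, a * 110:(a + 1) * 110] = 2.0
            truth.archetypes[0, 110:330] = 1.0
        expr = center_genes(generate_tumors(truth))
        return truth, expr

    def test_redundantly_supported_pathway_passes(self):
        from paretotasks.enrichment import leave_one_out_check
        from paretotasks.parti import fit_archetypes
        from paretotasks.preprocess import pca

        truth, expr = self._planted(diffuse=True)
        space = pca(expr, 2)
        arch = fit_archetypes(space.scores.to_numpy(), 3, seed=0)
        result = leave_one_out_check(expr, truth.archetype_blocks[0], arch,
                                     seed=0)
        assert result is True

    def test_single_support_vertex_fails_or_is_inconclusive(self):
        from paretotasks.enrichment import leave_one_out_check
        from paretotasks.parti import fit_archetypes
        from paretotasks.preprocess import pca

        truth, expr = self._planted(diffuse=False)
        space = pca(expr, 2)
        arch = fit_archetypes(space.scores.to_numpy(), 3, seed=0)
        result = leave_one_out_check(expr, truth.archetype_blocks[0], arch,
                                     seed=0)
        assert result is not True

    def test_small_pathway_not_applicable(self):
        from paretotasks.enrichment import leave_one_out_check
        from paretotasks.parti import fit_archetypes
        from paretotasks.preprocess import pca

        truth, expr = self._planted(diffuse=True)
        space = pca(expr, 2)
        arch = fit_archetypes(space.scores.to_numpy(), 3, seed=0)
        result = leave_one_out_check(expr, truth.archetype_blocks[0][:50],
                                     arch, seed=0)
        assert result is None
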