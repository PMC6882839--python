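"""Pooled fits across cancer types, profile clustering, archetype matching."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from paretotasks.preprocess import ExpressionMatrix
from paretotasks.synthetic import generate_tumors, make_truth
from paretotasks.universal import (
    ArchetypeProfile,
    cluster_archetype_profiles,
    match_all_archetypes,
    match_archetypes,
    pool_and_fit,
    type_composition_near_archetypes,
)


def _two_type_cohorts(offset_sd, seed=0, n=150):
    """Two cohorts from the same planted archetypes, differing tissue offsets."""
    truth = make_truth(n_samples=2 * n, n_archetypes=3, n_genes=80,
                       block_size=15, n_types=2, tissue_offset_sd=offset_sd,
                       dirichlet_concentration=0.3, noise_sd=0.05, seed=seed)
    expr = generate_tumors(truth)
    cohorts = []
    for t in ("TYPE0", "TYPE1"):
        idx = expr.metadata["cancer_type"] == t
        cohorts.append(ExpressionMatrix(expr.values.loc[idx],
                                        expr.metadata.loc[idx]))
    return truth, cohorts


class TestPoolAndFit:
    def test_per_type_centering_recovers_shared_archetypes(self):
        truth, cohorts = _two_type_cohorts(offset_sd=3.0, seed=1)
        fit, scores, types = pool_and_fit(cohorts, [3], n_shuffles=100, seed=2,
                                          n_restarts=2, max_iter=40)
        assert fit is not None and fit.k == 3
        # the planted pairwise archetype distances survive the pooled fit
        back = fit.archetypes
        found = sorted(np.linalg.norm(back[i] - back[j])
                       for i in range(3) for j in range(i + 1, 3))
        basis = truth.front_basis_genes()
        coords = (truth.archetypes - truth.archetypes[0]) @ basis
        planted = sorted(np.linalg.norm(coords[i] - coords[j])
                         for i in range(3) for j in range(i + 1, 3))
        np.testing.assert_allclose(found, planted, rtol=0.10)

    def test_single_cohort_reduces_to_per_type_pipeline(self):
        _, cohorts = _two_type_cohorts(offset_sd=0.0, seed=3)
        fit_single, scores_single, _ = pool_and_fit(cohorts[:1], [3],
                                                    n_shuffles=100, seed=4,
                                                    n_restarts=2, max_iter=40)
        assert fit_single is not None

    def test_same_seed_identical(self):
        _, cohorts = _two_type_cohorts(offset_sd=1.0, seed=5)
        f1, s1, _ = pool_and_fit(cohorts, [3], n_shuffles=100, seed=6,
                                 n_restarts=1, max_iter=30)
        f2, s2, _ = pool_and_fit(cohorts, [3], n_shuffles=100, seed=6,
                                 n_restarts=1, max_iter=30)
        np.testing.assert_array_equal(f1.archetypes, f2.archetypes)
        assert f1.p_value == f2.p_value

    def test_disjoint_gene_universes_rejected(self):
        _, cohorts = _two_type_cohorts(offset_sd=0.0, seed=7)
        renamed = ExpressionMatrix(
            cohorts[1].values.rename(columns=lambda g: f"other_{g}"),
            cohorts[1].metadata)
        with pytest.raises(ValueError):
            pool_and_fit([cohorts[0], renamed], [3])


class TestTypeComposition:
    def test_uniform_mixing_near_fraction(self):
        rng = np.random.default_rng(8)
        n = 600
        scores = pd.DataFrame(rng.uniform(-1, 1, size=(n, 2)),
                              index=[f"s{i}" for i in range(n)])
        types = pd.Series(rng.choice(["A", "B"], size=n), index=scores.index)
        arch = np.array([[1.0, 1.0], [-1.0, -1.0]])
        comp = type_composition_near_archetypes(scores, types, arch, 0.10)
        assert ((comp - 0.10).abs() < 0.05).all().all()

    def test_fraction_one_gives_all_ones(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(rng.normal(size=(50, 2)))
        types = pd.Series(["A"] * 25 + ["B"] * 25, index=scores.index)
        comp = type_composition_near_archetypes(scores, types,
                                                np.zeros((2, 2)), 1.0)
        np.testing.assert_allclose(comp.to_numpy(), 1.0)

    def test_specialist_type_detected(self):
        rng = np.random.default_rng(10)
        # type B sits at archetype 0; type A spreads uniformly
        a = rng.uniform(-1, 1, size=(300, 2))
        b = np.array([2.0, 2.0]) + 0.1 * rng.standard_normal((100, 2))
        scores = pd.DataFrame(np.vstack([a, b]),
                              index=[f"s{i}" for i in range(400)])
        types = pd.Series(["A"] * 300 + ["B"] * 100, index=scores.index)
        arch = np.array([[2.0, 2.0], [-1.0, -1.0]])
        comp = type_composition_near_archetypes(scores, types, arch, 0.10)
        assert comp.loc[0, "B"] > 0.3
        assert comp.loc[1, "B"] < 0.02


class TestClustering:
    def _profiles(self, centers, per_center, noise, seed=11, n_paths=12):
        rng = np.random.default_rng(seed)
        profiles = []
        paths = [f"P{i}" for i in range(n_paths)]
        for ci, center in enumerate(centers):
            for r in range(per_center):
                vec = pd.Series(center + noise * rng.standard_normal(n_paths),
                                index=paths)
                profiles.append(ArchetypeProfile(r, f"T{ci}_{r}", vec))
        return profiles

    def test_well_separated_planted_clusters_recovered(self):
        rng = np.random.default_rng(12)
        centers = [10.0 * rng.standard_normal(6) for _ in range(3)]
        profiles = self._profiles(centers, per_center=10, noise=0.3, n_paths=6)
        labels, n_comp = cluster_archetype_profiles(profiles, max_components=6,
                                                    seed=13)
        assert n_comp == 3
        # clusters must be pure by planted center
        for c in range(3):
            block = labels[c * 10: (c + 1) * 10]
            assert len(set(block)) == 1

    def test_identical_profiles_single_component(self):
        vec = pd.Series(np.ones(8), index=[f"P{i}" for i in range(8)])
        profiles = [ArchetypeProfile(i, f"T{i}", vec.copy()) for i in range(5)]
        _, n_comp = cluster_archetype_profiles(profiles, max_components=4,
                                               seed=14)
        assert n_comp == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        centers = [5.0 * rng.standard_normal(10) for _ in range(2)]
        profiles = self._profiles(centers, per_center=5, noise=0.5, n_paths=10)
        l1, _ = cluster_archetype_profiles(profiles, seed=16)
        l2, _ = cluster_archetype_profiles(profiles, seed=16)
        np.testing.assert_array_equal(l1, l2)


class TestMatching:
    def _profile(self, sets, source="T", aid=0):
        return ArchetypeProfile(aid, source, pd.Series(dtype=float), list(sets))

    def test_identical_sets_closed_form(self):
        universe = [f"P{i}" for i in range(100)]
        sets = universe[:20]
        p = match_archetypes(self._profile(sets), self._profile(sets), universe)
        assert p == pytest.approx(1.0 / comb(100, 20), rel=1e-9)

    def test_disjoint_sets_not_significant(self):
        universe = [f"P{i}" for i in range(40)]
        p = match_archetypes(self._profile(universe[:10]),
                             self._profile(universe[10:20]), universe)
        assert p > 0.5

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            match_archetypes(self._profile(["a"]), self._profile(["a"]), [])

    def test_each_task_assigned_at_most_once_per_type(self):
        universe = [f"P{i}" for i in range(60)]
        universal = [self._profile(universe[i * 15:(i + 1) * 15], "universal", i)
                     for i in range(3)]
        tissue = [self._profile(universe[i * 15:(i + 1) * 15] , "T1", i)
                  for i in range(3)]
        table = match_all_archetypes(tissue, universal,
                                     {"T1": universe}, alpha=0.01)
        matched = table[table["matched"]]
        assert len(matched) == 3
        # bijective: every tissue archetype found its own planted task
        assert (matched["tissue_archetype"].to_numpy()
                == matched["universal_archetype"].to_numpy()).all()


class TestArchetypeProfile:
    def test_planted_task_set_in_significant_sets(self):
        from paretotasks.preprocess import center_genes, pca
        from paretotasks.parti import fit_archetypes
        from paretotasks.synthetic import generate_gene_sets, generate_tumors, make_truth
        from paretotasks.universal import archetype_profile
        from scipy.optimize import linear_sum_assignment

        truth = make_truth(n_samples=250, n_archetypes=3, n_genes=120,
                           block_size=25, dirichlet_concentration=0.3,
                           noise_sd=0.1, seed=30)
        expr = center_genes(generate_tumors(truth))
        space = pca(expr, 2)
        arch = fit_archetypes(space.scores.to_numpy(), 3, seed=0)
        sets = generate_gene_sets(truth)
        # match fitted to planted archetypes
        mean = generate_tumors(truth).values.mean(axis=0).to_numpy()
        planted = (truth.archetypes - mean) @ space.loadings.to_numpy()
        cost = np.linalg.norm(arch[:, None, :] - planted[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        for fitted_id, planted_id in zip(rows, cols):
            profile = archetype_profile(expr, space.scores, arch[fitted_id],
                                        sets, fitted_id, "SYN")
            assert f"TASK_SET_{planted_id}" in profile.significant_sets
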