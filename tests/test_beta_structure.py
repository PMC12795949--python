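import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import pondiv as pv
from pondiv import DistanceMatrix

from conftest import small_community


def euclid_dm(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    labels = [f"p{i+1}" for i in range(pts.shape[0])]
    return DistanceMatrix(labels, squareform(pdist(pts)))


class TestBrayCurtis:
    def test_identical_zero(self):
        cm = small_community([[3, 2], [3, 2]])
        assert pv.bray_curtis(cm).d[0, 1] == 0.0

    def test_disjoint_one(self):
        cm = small_community([[3, 0], [0, 2]])
        assert pv.bray_curtis(cm).d[0, 1] == 1.0

    def test_hand_value(self):
        cm = small_community([[5, 5], [5, 0]])
        assert pv.bray_curtis(cm).d[0, 1] == pytest.approx(5 / 15)


class TestNmds:
    def test_three_equidistant_points_embed_exactly(self):
        dm = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        res = pv.nmds(dm, k=2, n_starts=8, seed=0)
        assert res.stress < 1e-6

    def test_self_embedding_recovers_configuration(self):
        rng = np.random.default_rng(10)
        dm = euclid_dm(rng.normal(size=(10, 2)))
        res = pv.nmds(dm, k=2, n_starts=16, max_iter=1000, seed=1)
        assert res.stress < 1e-4

    def test_more_dimensions_never_hurt(self, default_dataset):
        bc = pv.bray_curtis(default_dataset[0])
        s2 = pv.nmds(bc, k=2, n_starts=8, seed=2).stress
        s1 = pv.nmds(bc, k=1, n_starts=8, seed=2).stress
        assert s2 <= s1 + 1e-9


class TestPermanova:
    def test_one_dimensional_anova_equivalence_exact(self):
        dm = euclid_dm([0.0, 1.0, 10.0, 11.0])
        groups = {"p1": "A", "p2": "A", "p3": "B", "p4": "B"}
        res = pv.permanova(dm, groups, n_perm=99, seed=0)
        assert res.F == pytest.approx(200.0)
        assert res.R2 == pytest.approx(100 / 101)
        f_classic, _ = stats.f_oneway([0.0, 1.0], [10.0, 11.0])
        assert res.F == pytest.approx(f_classic)

    def test_matches_scikit_bio(self, default_dataset):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        cm = default_dataset[0]
        bc = pv.bray_curtis(cm)
        res = pv.permanova(bc, cm.region_of, n_perm=99, seed=1)
        sk_dm = skbio_stats.DistanceMatrix(bc.d, ids=bc.labels)
        sk = skbio_stats.permanova(
            sk_dm, grouping=[cm.region_of[p] for p in bc.labels], permutations=99
        )
        assert res.F == pytest.approx(float(sk["test statistic"]))

    def test_separated_clouds_r2_near_one(self):
        pts = [0.0, 0.01, 1000.0, 1000.01]
        dm = euclid_dm(pts)
        res = pv.permanova(dm, {"p1": "A", "p2": "A", "p3": "B", "p4": "B"}, 99, 0)
        assert res.R2 > 0.999

    def test_null_p_uniform(self):
        """Exchangeable labels give (super-)uniform permutation p-values."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(150):
            dm = euclid_dm(rng.normal(size=(8, 2)))
            groups = {f"p{i+1}": ("A" if i < 4 else "B") for i in range(8)}
            ps.append(pv.permanova(dm, groups, n_perm=49, seed=int(rng.integers(2**31))).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_errors(self):
        dm = euclid_dm([0.0, 1.0])
        with pytest.raises(ValueError):
            pv.permanova(dm, {"p1": "A", "p2": "A"}, 9, 0)


class TestBetaDispersion:
    def test_two_point_group_distances(self):
        dm = euclid_dm([0.0, 1.0])
        res = pv.beta_dispersion(dm, {"p1": "A", "p2": "A"})
        assert res.distances.tolist() == pytest.approx([0.5, 0.5])

    def test_symmetric_groups_f_zero(self):
        dm = euclid_dm([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        groups = {f"p{i+1}": ("A" if i < 3 else "B") for i in range(6)}
        res = pv.beta_dispersion(dm, groups)
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_distance_scaling_homogeneity(self):
        dm = euclid_dm([0.0, 1.0, 3.0])
        groups = {"p1": "A", "p2": "A", "p3": "A"}
        base = pv.beta_dispersion(dm, groups).distances
        doubled = pv.beta_dispersion(
            DistanceMatrix(dm.labels, 2 * dm.d), groups
        ).distances
        assert doubled.to_numpy() == pytest.approx(2 * base.to_numpy())


class TestBaselga:
    def test_identical_communities_zero(self):
        cm = small_community([[1, 1, 0], [1, 1, 0]])
        part = pv.baselga_pairwise(pv.to_presence_absence(cm))
        assert part.beta_sor.d[0, 1] == 0.0
        assert part.beta_sim.d[0, 1] == 0.0

    def test_nested_pair_pure_nestedness(self):
        cm = small_community([[1, 1, 1], [1, 0, 0]])
        part = pv.baselga_pairwise(cm)
        assert part.beta_sim.d[0, 1] == 0.0
        assert part.beta_sne.d[0, 1] == part.beta_sor.d[0, 1] > 0

    def test_hand_formula(self):
        # a=1 shared, b=1 unique to p1, c=2 unique to p2
        cm = small_community([[1, 1, 0, 0], [1, 0, 1, 1]])
        part = pv.baselga_pairwise(cm)
        assert part.beta_sim.d[0, 1] == pytest.approx(0.5)
        assert part.beta_sor.d[0, 1] == pytest.approx(0.6)
        assert part.beta_sne.d[0, 1] == pytest.approx(0.1)

    def test_partition_adds_up_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            x = rng.integers(0, 2, size=(2, 10))
            x[x.sum(axis=1) == 0, 0] = 1
            part = pv.baselga_pairwise(small_community(x))
            assert part.beta_sor.d[0, 1] == pytest.approx(
                part.beta_sim.d[0, 1] + part.beta_sne.d[0, 1], abs=1e-12
            )

    def test_multisite_reduces_to_pairwise_for_two_sites(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = rng.integers(0, 2, size=(2, 8))
            x[x.sum(axis=1) == 0, 0] = 1
            cm = small_community(x)
            multi = pv.baselga_multisite(cm)
            pair = pv.baselga_pairwise(cm)
            assert multi.beta_sim == pytest.approx(pair.beta_sim.d[0, 1])
            assert multi.beta_sor == pytest.approx(pair.beta_sor.d[0, 1])

    def test_multisite_three_site_toy_against_formula(self):
        """Independent evaluation of the multiple-site formulas via set ops."""
        sites = [{0, 1, 2, 3}, {2, 3, 4}, {0, 4, 5, 6}]
        x = np.zeros((3, 7), dtype=int)
        for i, s in enumerate(sites):
            x[i, list(s)] = 1
        cm = small_community(x)
        multi = pv.baselga_multisite(cm)
        sum_min = sum_max = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                bij = len(sites[i] - sites[j])
                bji = len(sites[j] - sites[i])
                sum_min += min(bij, bji)
                sum_max += max(bij, bji)
        a_term = sum(len(s) for s in sites) - len(set().union(*sites))
        sim = sum_min / (a_term + sum_min)
        sor = (sum_min + sum_max) / (2 * a_term + sum_min + sum_max)
        assert multi.beta_sim == pytest.approx(sim)
        assert multi.beta_sor == pytest.approx(sor)
        assert multi.beta_sne == pytest.approx(sor - sim)

    def test_all_identical_sites_zero(self):
        cm = small_community([[1, 1], [1, 1], [1, 1]])
        multi = pv.baselga_multisite(cm)
        assert (multi.beta_sim, multi.beta_sne, multi.beta_sor) == (0.0, 0.0, 0.0)


class TestRaupCrick:
    def test_full_pool_sites_at_most_half(self):
        cm = small_community([[1, 1, 1], [1, 1, 1]])
        res = pv.raup_crick(cm, n_rand=99, seed=0)
        assert res.beta_rc.d[0, 1] <= 0.5

    def test_exact_matches_brute_force_enumeration(self):
        """4-species pool, two sites of richness 2: exhaustive enumeration of
        all C(4,2)^2 equiprobable null pairs."""
        import itertools

        cm = small_community([[1, 1, 0, 0], [0, 1, 1, 0]])
        res = pv.raup_crick(cm, weighting="uniform", method="exact")
        obs_shared = 1
        shared_counts = [
            len(set(a) & set(b))
            for a in itertools.combinations(range(4), 2)
            for b in itertools.combinations(range(4), 2)
        ]
        expected = np.mean([s > obs_shared for s in shared_counts]) + 0.5 * np.mean(
            [s == obs_shared for s in shared_counts]
        )
        assert res.beta_rc.d[0, 1] == pytest.approx(expected)

    def test_montecarlo_approaches_exact(self):
        cm = small_community([[1, 1, 0, 0, 1], [0, 1, 1, 1, 0]])
        exact = pv.raup_crick(cm, weighting="uniform", method="exact")
        mc = pv.raup_crick(cm, n_rand=20000, seed=5, weighting="uniform")
        assert mc.beta_rc.d[0, 1] == pytest.approx(exact.beta_rc.d[0, 1], abs=0.02)

    def test_symmetric_and_column_order_invariant(self):
        x = np.array([[1, 1, 0, 0, 1], [0, 1, 1, 0, 0], [1, 0, 1, 1, 0]])
        cm = small_community(x)
        res = pv.raup_crick(cm, n_rand=199, seed=8)
        assert res.beta_rc.d == pytest.approx(res.beta_rc.d.T)
        perm = [4, 2, 0, 3, 1]
        res2 = pv.raup_crick(small_community(x[:, perm]), n_rand=199, seed=8)
        assert res2.beta_rc.d == pytest.approx(res.beta_rc.d, abs=0.15)

    def test_null_generator_centred_at_half(self):
        means = []
        for seed in range(6):
            cm, _, _ = pv.generate_null_pair(pv.GeneratorConfig(seed=seed))
            res = pv.raup_crick(pv.to_presence_absence(cm), n_rand=199, seed=seed)
            means.append(res.mean)
        assert abs(np.mean(means) - 0.5) < 0.05
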