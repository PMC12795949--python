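import numpy as np
import pandas as pd
import pytest

import pondiv as pv
from pondiv.functional_diversity import TraitSpace, pooled_functional_metrics


def trait_matrix(rows, species=None, traits=None):
    rows = np.asarray(rows)
    species = species or [f"s{i+1}" for i in range(rows.shape[0])]
    traits = traits or [f"t{j+1}" for j in range(rows.shape[1])]
    return pv.TraitMatrix(pd.DataFrame(rows, index=species, columns=traits))


def space_from(coords):
    coords = np.asarray(coords, dtype=float)
    return TraitSpace(
        species=[f"s{i+1}" for i in range(coords.shape[0])],
        coords=coords,
        axes_retained=coords.shape[1],
        variance_explained=np.zeros(coords.shape[1]),
    )


class TestGower:
    def test_identical_rows_zero(self):
        tm = trait_matrix([[1, 0, 1], [1, 0, 1]])
        assert pv.gower_distance(tm).d[0, 1] == 0.0

    def test_complementary_rows_one(self):
        tm = trait_matrix([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert pv.gower_distance(tm).d[0, 1] == 1.0

    def test_half_mismatch(self):
        tm = trait_matrix([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert pv.gower_distance(tm).d[0, 1] == pytest.approx(0.5)


class TestPcaReduce:
    def test_two_species_one_axis(self):
        tm = trait_matrix([[1, 0, 1], [0, 1, 1]])
        space = pv.pca_reduce(tm)
        assert space.axes_retained == 1

    def test_variance_fractions_sum_to_one(self, default_dataset):
        space = pv.pca_reduce(default_dataset[1])
        assert space.variance_explained.sum() == pytest.approx(1.0)

    def test_full_rank_scores_preserve_distances(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=(12, 5))
        x[:, 0] = 1 - x[:, 1].clip(max=1)  # avoid all-zero rows
        x[x.sum(axis=1) == 0, 0] = 1
        tm = trait_matrix(x)
        space = pv.pca_reduce(tm, max_axes=5)
        xc = x - x.mean(axis=0)
        from scipy.spatial.distance import pdist

        assert pdist(space.coords) == pytest.approx(pdist(xc))

    def test_single_species_errors(self):
        with pytest.raises(ValueError):
            pv.pca_reduce(trait_matrix([[1, 0]]))


class TestFunctionalRichness:
    def test_unit_square(self):
        space = space_from([[0, 0], [1, 0], [0, 1], [1, 1]])
        assert pv.functional_richness(space, space.species) == pytest.approx(1.0)

    def test_one_dimension_is_range(self):
        space = space_from([[0.0], [3.0]])
        assert pv.functional_richness(space, space.species) == pytest.approx(3.0)

    def test_hull_below_bounding_box(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        space = space_from(pts)
        vol = pv.functional_richness(space, space.species)
        bbox = np.prod(pts.max(axis=0) - pts.min(axis=0))
        assert 0 < vol <= bbox

    def test_interior_point_changes_nothing(self):
        square = [[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]]
        space = space_from(square)
        v_all = pv.functional_richness(space, space.species)
        v_hull = pv.functional_richness(space, space.species[:4])
        assert v_all == pytest.approx(v_hull)

    def test_single_species_undefined(self):
        space = space_from([[0.0, 0.0]])
        assert pv.functional_richness(space, space.species) is None

    def test_rotation_invariant(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        v1 = pv.functional_richness(space_from(pts), [f"s{i+1}" for i in range(8)])
        v2 = pv.functional_richness(space_from(pts @ q), [f"s{i+1}" for i in range(8)])
        assert v1 == pytest.approx(v2)


class TestFunctionalDispersion:
    def test_single_species_zero(self):
        space = space_from([[2.0, 1.0]])
        assert pv.functional_dispersion(space, ["s1"], [5.0]) == 0.0

    def test_two_species_half_distance(self):
        space = space_from([[0.0, 0.0], [3.0, 4.0]])
        fdis = pv.functional_dispersion(space, space.species, [1.0, 1.0])
        assert fdis == pytest.approx(2.5)  # distance 5, centroid midway

    def test_abundance_scale_invariant(self):
        space = space_from([[0.0], [1.0], [4.0]])
        w = [1.0, 2.0, 3.0]
        a = pv.functional_dispersion(space, space.species, w)
        b = pv.functional_dispersion(space, space.species, [2 * x for x in w])
        assert a == pytest.approx(b)

    def test_translation_invariant(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        w = rng.random(6) + 0.1
        sp = [f"s{i+1}" for i in range(6)]
        a = pv.functional_dispersion(space_from(pts), sp, w)
        b = pv.functional_dispersion(space_from(pts + 10.0), sp, w)
        assert a == pytest.approx(b)


class TestFunctionalDivergence:
    def test_equidistant_species_give_one(self):
        space = space_from([[1, 0], [0, 1], [-1, 0], [0, -1]])
        fdiv = pv.functional_divergence(space, space.species, [0.1, 0.2, 0.3, 0.4])
        assert fdiv == pytest.approx(1.0)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(7, 3))
            w = rng.random(7) + 0.01
            sp = [f"s{i+1}" for i in range(7)]
            fdiv = pv.functional_divergence(space_from(pts), sp, w)
            assert 0.0 <= fdiv <= 1.0

    def test_four_point_hand_computation(self):
        """Triangle plus interior point, unequal weights, against an
        independent step-by-step evaluation of the divergence formula."""
        pts = np.array([[0, 0], [2, 0], [0, 2], [0.5, 0.5]], dtype=float)
        w = np.array([0.1, 0.2, 0.3, 0.4])
        space = space_from(pts)
        fdiv = pv.functional_divergence(space, space.species, w)
        g = pts[:3].mean(axis=0)  # hull vertices are the triangle corners
        d = np.linalg.norm(pts - g, axis=1)
        dbar = d.mean()
        expected = (w @ (d - dbar) + dbar) / (w @ np.abs(d - dbar) + dbar)
        assert fdiv == pytest.approx(expected)

    def test_too_few_species_undefined(self):
        space = space_from([[0, 0], [1, 1]])
        assert pv.functional_divergence(space, space.species, [1, 1]) is None


class TestSiteIndices:
    def test_undefined_flags_by_species_count(self, aligned):
        fi = pv.site_functional_indices(aligned)
        t = fi.table
        assert (t.loc[t.n_species_used >= 3, "FDiv"].notna()).all()
        assert (t.loc[t.n_species_used >= 2, "FDis"].notna()).all()

    def test_pooled_fric_bounds_pond_fric(self, aligned):
        """Region-pooled hull contains every pond hull (same trait space)."""
        region = aligned.community.regions[0]
        ds = pv.align(aligned.community, aligned.traits, scope=region)
        space = pv.pca_reduce(ds.traits)
        pooled = pooled_functional_metrics(ds, space, ds.community.ponds)
        fi = pv.site_functional_indices(ds)
        assert pooled["FRic"] >= fi.table["FRic"].max() - 1e-12

    def test_full_pond_equals_whole_space(self):
        counts = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 0, 0]],
            index=["p1", "p2"], columns=["s1", "s2", "s3", "s4"],
        )
        cm = pv.CommunityMatrix(counts, {"p1": "A", "p2": "A"})
        tm = trait_matrix(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
            species=["s1", "s2", "s3", "s4"],
        )
        ds = pv.align(cm, tm)
        space = pv.pca_reduce(ds.traits)
        fi = pv.site_functional_indices(ds)
        whole = pv.functional_richness(space, ds.community.species)
        assert fi.table.loc["p1", "FRic"] == pytest.approx(whole)


class TestFunctionalRarefaction:
    def test_final_step_is_pooled_value_with_zero_sd(self, aligned):
        region = aligned.community.regions[0]
        ds = pv.align(aligned.community, aligned.traits, scope=region)
        curves = pv.functional_rarefaction(ds, n_reps=10, seed=7)
        space = pv.pca_reduce(ds.traits)
        pooled = pooled_functional_metrics(ds, space, ds.community.ponds)
        for m, curve in curves.items():
            assert curve.sd[-1] == pytest.approx(0.0, abs=1e-12)
            assert curve.mean_richness[-1] == pytest.approx(pooled[m])

    def test_fric_curve_monotone(self, aligned):
        """Pooling ponds only adds hull points in a fixed space."""
        region = aligned.community.regions[1]
        ds = pv.align(aligned.community, aligned.traits, scope=region)
        curves = pv.functional_rarefaction(ds, n_reps=10, seed=8)
        assert (np.diff(curves["FRic"].mean_richness) >= -1e-9).all()


class TestFunctionalAucTest:
    def test_null_rejection_rate_controlled(self):
        """With identical trait generation in both regions the FRic-AUC
        permutation test stays near its nominal 5% size (30 exchangeable
        datasets at reduced problem size; Monte-Carlo bound)."""
        rejections = 0
        n = 30
        for seed in range(n):
            cfg = pv.GeneratorConfig(
                n_ponds_per_region=6, pool_size={"A": 25, "B": 25}, seed=seed
            )
            cm, tm, _ = pv.generate_null_pair(cfg)
            ds = pv.align(cm, tm)
            ra, rb = cm.regions
            res = pv.functional_auc_permutation_test(
                ds, ra, rb, n_perm=49, n_reps=4, seed=seed + 500
            )
            rejections += res.p_value <= 0.05
        # true size 0.05: P(>5/30 rejections) < 1e-3
        assert rejections <= 5
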