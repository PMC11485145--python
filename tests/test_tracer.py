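import numpy as np
import pytest

import cingfp as cf
from cingfp.errors import CapacityError, InsufficientDataError, ValidationError
from cingfp.synthetic import LIMBIC_TARGETS
from cingfp.tracer import (
    ProjectionMatrix,
    SeedSpec,
    place_seeds,
    projection_similarity,
    sample_density,
    stack_densities,
    tracer_fingerprint,
)

from .conftest import naive_pearson


class TestPlaceSeeds:
    def test_even_rank_quantiles_on_straight_strip(self, straight_strip_atlas):
        spec = place_seeds(straight_strip_atlas, [1], 10)
        ranks = [vs[0][1] for vs in spec.voxel_sets]  # AP coordinate = rank here
        assert ranks == [4, 14, 24, 34, 44, 54, 64, 74, 84, 94]
        np.testing.assert_allclose(spec.u, np.arange(0.05, 1.0, 0.1), atol=1e-12)

    def test_all_voxels_when_n_equals_roi_size(self, straight_strip_atlas):
        spec = place_seeds(straight_strip_atlas, [1], 100)
        assert spec.n_seeds == 100
        assert {vs[0][1] for vs in spec.voxel_sets} == set(range(100))

    def test_single_seed_at_median_rank(self, straight_strip_atlas):
        spec = place_seeds(straight_strip_atlas, [1], 1)
        assert spec.voxel_sets[0][0][1] == 49
        assert spec.u[0] == pytest.approx(0.5)

    def test_capacity_error(self, straight_strip_atlas):
        with pytest.raises(CapacityError):
            place_seeds(straight_strip_atlas, [1], 101)

    def test_radius_grows_seed_within_roi(self, atlas_small):
        strip = atlas_small.ids_with_role("seed_roi")
        spec = place_seeds(atlas_small, strip, 3, radius=1)
        assert all(len(vs) > 1 for vs in spec.voxel_sets)
        mask = atlas_small.mask_of(strip)
        for vs in spec.voxel_sets:
            assert mask[vs[:, 0], vs[:, 1], vs[:, 2]].all()

    def test_seed_spec_rejects_overlapping_sets(self):
        with pytest.raises(ValidationError):
            SeedSpec(
                [np.array([[0, 0, 0]]), np.array([[0, 0, 0]])], np.array([0.2, 0.8])
            )


class TestSampleDensity:
    def test_values(self, atlas_small, rules_small):
        exps = cf.simulate_tracer_experiments(atlas_small, rules_small, 3, rng_seed=0)
        single = np.array([[1, 1, 1]])
        pair = np.array([[1, 1, 1], [2, 2, 2]])
        pm = sample_density(exps, [single, pair])
        d0 = exps[0].density.data
        assert pm.values[0, 0] == pytest.approx(d0[1, 1, 1])
        assert pm.values[0, 1] == pytest.approx((d0[1, 1, 1] + d0[2, 2, 2]) / 2)

    def test_two_voxel_mean_is_arithmetic(self):
        from cingfp.core_io import VolumeGrid
        from cingfp.synthetic import TracerExperiment

        dens = np.zeros((3, 3, 3))
        dens[0, 0, 0], dens[1, 0, 0] = 1.0, 3.0
        exp = TracerExperiment(VolumeGrid(dens), np.zeros((3, 3, 3), bool), 0.5)
        pm = sample_density([exp], [np.array([[0, 0, 0], [1, 0, 0]])])
        assert pm.values[0, 0] == pytest.approx(2.0)

    def test_all_zero_experiment_gives_zero_row(self):
        from cingfp.core_io import VolumeGrid
        from cingfp.synthetic import TracerExperiment

        exp = TracerExperiment(
            VolumeGrid(np.zeros((3, 3, 3))), np.zeros((3, 3, 3), bool), 0.5
        )
        pm = sample_density([exp], [np.array([[0, 0, 0]]), np.array([[1, 1, 1]])])
        np.testing.assert_array_equal(pm.values, 0.0)

    def test_empty_location_raises(self, atlas_small, rules_small):
        exps = cf.simulate_tracer_experiments(atlas_small, rules_small, 1, rng_seed=0)
        with pytest.raises(ValidationError):
            sample_density(exps, [np.empty((0, 3), dtype=int)])

    def test_projection_matrix_rejects_negative(self):
        with pytest.raises(ValidationError):
            ProjectionMatrix(np.array([[-1.0]]), [0])


class TestProjectionSimilarity:
    def _pm(self, arr):
        return ProjectionMatrix(np.asarray(arr, float), list(range(np.shape(arr)[1])))

    def test_identical_column_r_one(self):
        col = np.array([[1.0], [2.0], [5.0], [3.0]])
        sim = projection_similarity(self._pm(col), self._pm(col))
        assert sim.values[0, 0] == pytest.approx(1.0)

    def test_negated_shifted_column_r_minus_one(self):
        seed = np.array([[1.0], [2.0], [5.0], [3.0]])
        brain = 10.0 - 2.0 * seed
        sim = projection_similarity(self._pm(seed), self._pm(brain))
        assert sim.values[0, 0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        seed = np.array([[1.0], [2.0], [3.0], [4.0]])
        brain = np.array([[1.0], [3.0], [2.0], [4.0]])
        sim = projection_similarity(self._pm(seed), self._pm(brain))
        assert sim.values[0, 0] == pytest.approx(0.8)

    def test_requires_three_experiments(self):
        two = np.ones((2, 1))
        with pytest.raises(InsufficientDataError):
            projection_similarity(self._pm(two), self._pm(two))

    def test_constant_column_gives_nan(self):
        seed = np.array([[1.0], [2.0], [3.0]])
        brain = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        sim = projection_similarity(self._pm(seed), self._pm(brain))
        assert np.isnan(sim.values[0, 0])
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        seeds = rng.random((5, 4))
        brain = rng.random((5, 20))
        sim = projection_similarity(self._pm(seeds), self._pm(brain))
        np.testing.assert_allclose(sim.values, naive_pearson(seeds, brain), atol=1e-10)

    def test_invariant_under_location_affine_rescale(self):
        rng = np.random.default_rng(1)
        seeds = rng.random((6, 3))
        brain = rng.random((6, 5))
        base = projection_similarity(self._pm(seeds), self._pm(brain)).values
        brain2 = brain.copy()
        brain2[:, 2] = 3.0 * brain2[:, 2] + 7.0  # rescale one location
        again = projection_similarity(self._pm(seeds), self._pm(brain2)).values
        np.testing.assert_allclose(again, base, atol=1e-10)

    def test_values_bounded(self):
        rng = np.random.default_rng(2)
        sim = projection_similarity(
            self._pm(rng.random((8, 5))), self._pm(rng.random((8, 30)))
        )
        assert np.nanmax(np.abs(sim.values)) <= 1.0


class TestTracerFingerprint:
    @pytest.fixture(scope="class")
    def fingerprint_inputs(self, atlas_default, tracer_collection):
        _, experiments, _ = tracer_collection
        seeds = place_seeds(atlas_default, [1], 10)
        seed_pm = sample_density(experiments, seeds.voxel_sets)
        brain_pm = stack_densities(experiments)
        sim_seeds = projection_similarity(seed_pm, brain_pm, atlas_default.shape)
        tgt = atlas_default.table[
            (atlas_default.table["role"] == "target")
            & (atlas_default.table["hemisphere"] == "L")
        ]
        names = [n.removesuffix("_L") for n in tgt["name"]]
        locs = [atlas_default.voxels_of(int(i)) for i in tgt["label_id"]]
        sim_targets = projection_similarity(
            sample_density(experiments, locs, names), brain_pm, atlas_default.shape
        )
        exclusion = atlas_default.mask_of(
            [1] + atlas_default.ids_with_role("target")
        )
        return seeds, sim_seeds, sim_targets, names, exclusion

    def test_self_correlation_entry_is_one(self, fingerprint_inputs):
        seeds, sim_seeds, _, names, exclusion = fingerprint_inputs
        fp = tracer_fingerprint(
            sim_seeds, sim_seeds, exclusion, seeds.u, [f"s{i}" for i in range(10)]
        )
        np.testing.assert_allclose(np.diag(fp.mean_r), 1.0, atol=1e-12)

    def test_anterior_seed_peaks_at_limbic_target(self, fingerprint_inputs):
        seeds, sim_seeds, sim_targets, names, exclusion = fingerprint_inputs
        fp = tracer_fingerprint(
            sim_seeds, sim_targets, exclusion, seeds.u, names, species="mouse"
        )
        assert names[int(np.argmax(fp.mean_r[0]))] in LIMBIC_TARGETS
        assert np.all(np.isnan(fp.sem))
        assert fp.n_subjects == 1

    def test_zone_grouping_of_fingerprint_rows(self, fingerprint_inputs):
        # rows of seeds in the same planted zone are more alike (cosine)
        # than rows of seeds in different zones
        seeds, sim_seeds, sim_targets, names, exclusion = fingerprint_inputs
        fp = tracer_fingerprint(sim_seeds, sim_targets, exclusion, seeds.u, names)
        rows = fp.mean_r / np.linalg.norm(fp.mean_r, axis=1, keepdims=True)
        cos = rows @ rows.T
        zone = np.digitize(seeds.u, [1 / 3, 2 / 3])
        same = [cos[i, j] for i in range(10) for j in range(i) if zone[i] == zone[j]]
        diff = [cos[i, j] for i in range(10) for j in range(i) if zone[i] != zone[j]]
        assert np.mean(same) > np.mean(diff)

    def test_insufficient_support_raises(self, fingerprint_inputs):
        seeds, sim_seeds, sim_targets, names, _ = fingerprint_inputs
        all_excluded = np.ones(
            (40, 60, 30), dtype=bool
        )
        with pytest.raises(InsufficientDataError):
            tracer_fingerprint(sim_seeds, sim_targets, all_excluded, seeds.u, names)


class TestPlaceSeedsProperties:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_roi=st.integers(min_value=1, max_value=120),
        n_seeds=st.integers(min_value=1, max_value=120),
    )
    def test_rank_quantile_invariants(self, n_roi, n_seeds):
        """Seeds are in-ROI, disjoint, and strictly ordered in u for any
        ROI size and seed count that fits."""
        import pandas as pd

        from cingfp.core_io import LabelAtlas

        if n_seeds > n_roi:
            return
        labels = np.zeros((3, n_roi, 3), dtype=np.int32)
        labels[1, :, 1] = 1
        atlas = LabelAtlas(
            labels,
            pd.DataFrame(
                {"label_id": [1], "name": ["roi"], "hemisphere": ["M"],
                 "role": ["seed_roi"]}
            ),
        )
        spec = place_seeds(atlas, [1], n_seeds)
        assert spec.n_seeds == n_seeds
        ranks = [vs[0][1] for vs in spec.voxel_sets]
        assert len(set(ranks)) == n_seeds  # disjoint single-voxel seeds
        assert all(0 <= r < n_roi for r in ranks)
        assert np.all(np.diff(spec.u) > 0)
        assert np.all((spec.u > 0) & (spec.u <= 1))
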