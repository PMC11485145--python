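import dataclasses

import numpy as np
import pytest

import cingfp as cf
from cingfp.core_io import AP_AXIS
from cingfp.errors import ConfigError, PlacementError, ValidationError
from cingfp.synthetic import (
    TracerZone,
    default_bold_model,
    expected_same_network_r,
    iter_rsfmri_scans,
    phantom_brain_mask,
    strip_voxel_u,
)
from cingfp.tracer import sample_density


class TestPhantomAtlas:
    def test_default_label_inventory(self, atlas_default):
        roles = atlas_default.table["role"].value_counts().to_dict()
        assert roles["seed_roi"] == 1
        assert roles["target"] == 18  # 9 bilateral pairs
        assert roles["sensory"] == 2 and roles["dmn"] == 2

    def test_strip_spans_most_of_rostrocaudal_axis(self, atlas_default):
        strip = atlas_default.ids_with_role("seed_roi")[0]
        ys = atlas_default.voxels_of(strip)[:, AP_AXIS]
        extent = ys.max() - ys.min() + 1
        assert extent >= 0.8 * atlas_default.shape[AP_AXIS]

    def test_bilateral_targets_mirrored(self, atlas_default):
        left = atlas_default.voxels_of(atlas_default.id_of("amygdala_L"))
        right = atlas_default.voxels_of(atlas_default.id_of("amygdala_R"))
        nx = atlas_default.shape[0]
        mirrored = left.copy()
        mirrored[:, 0] = 2 * (nx // 2) - left[:, 0]
        assert set(map(tuple, mirrored)) == set(map(tuple, right))

    def test_deterministic_given_seed(self):
        a = cf.build_phantom_atlas((24, 40, 16), n_targets=4, rng_seed=7)
        b = cf.build_phantom_atlas((24, 40, 16), n_targets=4, rng_seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.table.equals(b.table)

    def test_strip_only_atlas_valid(self):
        atlas = cf.build_phantom_atlas(
            (24, 40, 16), n_targets=0, include_qc_labels=False
        )
        assert atlas.ids_with_role("target") == []
        assert atlas.ids_with_role("seed_roi") == [1]

    def test_too_small_grid_raises(self):
        with pytest.raises(PlacementError):
            cf.build_phantom_atlas((6, 10, 4))

    def test_brain_mask_contains_all_labels(self, atlas_default):
        brain = phantom_brain_mask(atlas_default)
        assert np.all(brain[atlas_default.labels > 0])
        assert brain.sum() < atlas_default.labels.size  # some air exists

    def test_strip_u_ascending_along_ap(self, atlas_default):
        vox, u = strip_voxel_u(atlas_default)
        assert np.all(np.diff(vox[:, AP_AXIS]) >= 0)
        assert np.all(np.diff(u) > 0)
        assert u[0] > 0 and u[-1] == pytest.approx(1.0)


class TestTracerGenerator:
    def test_determinism(self, atlas_small, rules_small):
        a = cf.simulate_tracer_experiments(atlas_small, rules_small, 5, rng_seed=3)
        b = cf.simulate_tracer_experiments(atlas_small, rules_small, 5, rng_seed=3)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.density.data, eb.density.data)
            assert ea.injection_u == eb.injection_u

    def test_densities_nonnegative_and_count(self, atlas_small, rules_small):
        exps = cf.simulate_tracer_experiments(atlas_small, rules_small, 50, rng_seed=1)
        assert len(exps) == 50
        assert all(e.density.data.min() >= 0 for e in exps)

    def test_target_density_closed_form(self, atlas_small):
        # noiseless, crosstalk off: density in a zone target is exactly
        # sum of zone gains plus background
        rules = dataclasses.replace(
            cf.default_tracer_rules(noise_sd=0.0),
            zones=(TracerZone(0.5, 0.1, ("amygdala",), strength=2.0),),
            crosstalk=0.0,
            efficacy_sd=0.0,
        )
        exps = cf.simulate_tracer_experiments(atlas_small, rules, 7, rng_seed=0)
        amy = atlas_small.voxels_of(atlas_small.id_of("amygdala_L"))
        dens = sample_density(exps, [amy]).values[:, 0]
        expected = [
            2.0 * np.exp(-((e.injection_u - 0.5) ** 2) / (2 * 0.1**2))
            + rules.background_density
            for e in exps
        ]
        np.testing.assert_allclose(dens, expected, atol=1e-12)

    def test_unlisted_target_gets_background_exactly(self, atlas_small):
        rules = dataclasses.replace(
            cf.default_tracer_rules(noise_sd=0.0),
            zones=(TracerZone(0.0, 0.1, ("amygdala",)),),
            crosstalk=0.0,
            efficacy_sd=0.0,
            halo_radius=0,
        )
        exps = cf.simulate_tracer_experiments(atlas_small, rules, 3, rng_seed=0)
        cp = atlas_small.voxels_of(atlas_small.id_of("caudoputamen_L"))
        dens = sample_density(exps, [cp]).values[:, 0]
        np.testing.assert_allclose(dens, rules.background_density, atol=1e-12)

    def test_narrower_zone_reduces_far_delivery(self, atlas_small):
        # tracer monotonicity: shrinking u_width strictly reduces the
        # density delivered to a zone target by distant injections
        def mean_far_density(width):
            rules = dataclasses.replace(
                cf.default_tracer_rules(noise_sd=0.0),
                zones=(TracerZone(0.0, width, ("amygdala",)),),
                crosstalk=0.0,
                efficacy_sd=0.0,
            )
            exps = cf.simulate_tracer_experiments(atlas_small, rules, 9, rng_seed=2)
            amy = atlas_small.voxels_of(atlas_small.id_of("amygdala_L"))
            far = [e for e in exps if abs(e.injection_u - 0.0) > width]
            return sample_density(far, [amy]).values[:, 0].mean()

        assert mean_far_density(0.05) < mean_far_density(0.15)

    def test_unknown_target_label_raises(self, atlas_small):
        rules = dataclasses.replace(
            cf.default_tracer_rules(),
            zones=(TracerZone(0.5, 0.1, ("thalamus_of_oz",)),),
        )
        with pytest.raises(ConfigError):
            cf.simulate_tracer_experiments(atlas_small, rules, 2)

    def test_zone_validation(self):
        with pytest.raises(ConfigError):
            TracerZone(1.5, 0.1, ("amygdala",))
        with pytest.raises(ConfigError):
            TracerZone(0.5, -0.1, ("amygdala",))


class TestBoldGenerator:
    def test_same_network_correlation_matches_closed_form(self, atlas_small):
        model = default_bold_model(atlas_small, signal_sd=1.0, noise_sd=1.0)
        assert expected_same_network_r(1.0, 1.0) == pytest.approx(0.5)
        scans, _ = cf.simulate_rsfmri_scans(
            atlas_small, model, 1, 2000, rng_seed=11
        )
        amy = atlas_small.flat_voxels_of(atlas_small.id_of("amygdala_L"))
        v1, v2 = scans[0].data[amy[0]], scans[0].data[amy[1]]
        r = np.corrcoef(v1, v2)[0, 1]
        assert 0.45 <= r <= 0.55

    def test_cross_network_block_covariance(self, atlas_small):
        # empirical correlations match the block model within 3/sqrt(T)
        T = 1200
        model = default_bold_model(atlas_small, signal_sd=1.0, noise_sd=1.0)
        scans, _ = cf.simulate_rsfmri_scans(atlas_small, model, 1, T, rng_seed=4)
        tol = 3.0 / np.sqrt(T)
        amy = atlas_small.flat_voxels_of(atlas_small.id_of("amygdala_L"))[0]
        cp = atlas_small.flat_voxels_of(atlas_small.id_of("caudoputamen_L"))[0]
        nac = atlas_small.flat_voxels_of(atlas_small.id_of("nucleus_accumbens_L"))[0]
        d = scans[0].data
        assert abs(np.corrcoef(d[amy], d[cp])[0, 1]) <= tol  # different networks
        assert abs(np.corrcoef(d[amy], d[nac])[0, 1] - 0.5) <= tol  # same network

    def test_homotopic_sensory_pair_shares_latent(self, atlas_small):
        model = default_bold_model(atlas_small, signal_sd=2.0, noise_sd=0.5)
        scans, _ = cf.simulate_rsfmri_scans(atlas_small, model, 1, 800, rng_seed=5)
        L = atlas_small.flat_voxels_of(atlas_small.id_of("sensory_L"))[0]
        R = atlas_small.flat_voxels_of(atlas_small.id_of("sensory_R"))[0]
        r = np.corrcoef(scans[0].data[L], scans[0].data[R])[0, 1]
        assert r > 0.8

    def test_anticorrelated_pair_limit(self, atlas_small):
        model = default_bold_model(atlas_small, signal_sd=1.0, noise_sd=1e-4)
        scans, _ = cf.simulate_rsfmri_scans(atlas_small, model, 1, 300, rng_seed=6)
        sens = atlas_small.flat_voxels_of(atlas_small.id_of("sensory_L"))[0]
        dmn = atlas_small.flat_voxels_of(atlas_small.id_of("dmn_L"))[0]
        r = np.corrcoef(scans[0].data[sens], scans[0].data[dmn])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-3)

    def test_frac_bad_one_flags_all(self, atlas_small):
        model = default_bold_model(atlas_small, frac_bad=1.0)
        _, manifest = cf.simulate_rsfmri_scans(atlas_small, model, 4, 32, rng_seed=0)
        assert manifest["bad_flag"].all()

    def test_determinism_and_streaming_equivalence(self, atlas_small):
        model = default_bold_model(atlas_small, frac_bad=0.5)
        scans_a, man_a = cf.simulate_rsfmri_scans(atlas_small, model, 3, 40, rng_seed=9)
        streamed = list(iter_rsfmri_scans(atlas_small, model, 3, 40, 1.0, rng_seed=9))
        for (scan_b, bad_b), scan_a, bad_a in zip(
            streamed, scans_a, man_a["bad_flag"]
        ):
            np.testing.assert_array_equal(scan_a.data, scan_b.data)
            assert bad_a == bad_b

    def test_too_few_timepoints_rejected(self, atlas_small):
        model = default_bold_model(atlas_small)
        with pytest.raises(ValidationError):
            cf.simulate_rsfmri_scans(atlas_small, model, 1, 8)

    def test_unassigned_target_label_rejected(self, atlas_small):
        model = default_bold_model(atlas_small)
        assignment = dict(model.network_assignment)
        assignment.pop(atlas_small.id_of("amygdala_L"))
        broken = dataclasses.replace(model, network_assignment=assignment)
        with pytest.raises(ConfigError):
            broken.validate(atlas_small)
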