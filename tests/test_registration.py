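"""RPE flattening, per-layer depth scaling, transverse registration."""

import dataclasses

import numpy as np
import pytest

import octapr as op
from octapr.phantom import LayerParams, PhantomConfig
from octapr.registration import flatten_shifts

from conftest import constant_layer_model


def volume_with_flow(layers, planes, shape=(8, 6, 140)):
    refl = np.full(shape, 1.0, dtype=np.float32)
    deco = np.zeros(shape, dtype=np.float32)
    for z in planes:
        deco[:, :, z] = 0.5
    return op.OctaVolume(refl, deco, (15.0, 15.0, 3.1))


class TestFlatten:
    def test_flat_rpe_is_identity(self):
        layers = constant_layer_model()
        vol = volume_with_flow(layers, [40])
        res = op.flatten_to_rpe(vol, layers)
        np.testing.assert_array_equal(res.volume.decorrelation, vol.decorrelation)
        assert not res.clipped_columns.any()

    def test_tilted_rpe_becomes_constant_and_content_shifts(self):
        shape = (10, 4)
        tilt = np.linspace(0, 10, shape[0])[:, None] * np.ones((1, shape[1]))
        layers = op.LayerModel(
            {k: v + tilt for k, v in constant_layer_model(shape).surfaces.items()}
        )
        vol = volume_with_flow(layers, [], shape=(*shape, 140))
        deco = vol.decorrelation.copy()
        for ix in range(shape[0]):
            deco[ix, :, 40 + int(round(tilt[ix, 0]))] = 0.5
        vol = op.OctaVolume(vol.reflectance, deco, vol.voxel_spacing)
        res = op.flatten_to_rpe(vol, layers)
        assert np.ptp(np.round(res.layers.surface("RPE"))) == 0
        flow_planes = {int(np.nonzero(res.volume.decorrelation[ix, 0])[0][0])
                       for ix in range(shape[0])}
        assert len(flow_planes) == 1  # all columns aligned

    def test_flatten_is_idempotent(self, demo_products):
        truth = demo_products["truth"]
        vol = demo_products["volume"]
        once = op.flatten_to_rpe(vol, truth.layer_model)
        twice = op.flatten_to_rpe(once.volume, once.layers)
        np.testing.assert_array_equal(
            once.volume.decorrelation, twice.volume.decorrelation
        )


class TestNormalizeDepth:
    def test_reference_equals_source_is_identity(self):
        layers = constant_layer_model()
        vol = volume_with_flow(layers, [40, 65])
        nvol = op.normalize_depth(vol, layers, layers)
        np.testing.assert_array_equal(nvol.volume.decorrelation, vol.decorrelation)
        np.testing.assert_allclose(
            nvol.volume.reflectance, vol.reflectance, atol=1e-6
        )

    def test_double_thickness_inl_compresses_features(self):
        ref = constant_layer_model()  # INL 57..72 (15 voxels)
        src = constant_layer_model(
            **{"INL/OPL": 87.0, "OPL/ONL": 97.0, "RPE": 135.0}
        )  # INL 57..87 (30 voxels)
        vol = volume_with_flow(src, [72])  # feature mid-INL of the source
        nvol = op.normalize_depth(vol, src, ref)
        plane = int(np.nonzero(nvol.volume.decorrelation[4, 3])[0][0])
        assert abs(plane - 64.5) <= 1.0  # mid-INL of the reference

    def test_degenerate_source_layer_flags_column(self):
        ref = constant_layer_model()
        src = constant_layer_model()
        src.surfaces["INL/OPL"][3, 2] = src.surfaces["IPL/INL"][3, 2]  # zero INL
        vol = volume_with_flow(src, [40])
        nvol = op.normalize_depth(vol, src, ref)
        assert nvol.invalid_columns[3, 2]
        assert not nvol.invalid_columns[0, 0]

    def test_thickness_variants_align_peaks_within_one_plane(self):
        # two phantoms differing only in layer thicknesses, normalized to
        # the same reference anatomy, put their plexus sheets at the same
        # normalized planes
        base = PhantomConfig.flat_macular(seed=4, grid_shape=(80, 48, 176))
        thick = dataclasses.replace(
            base,
            layer_params=LayerParams(
                pit_depth_um=0, nfl_peak_gain_um=0, gclipl_um=110.0, inl_um=38.0
            ),
        )
        ref_layers = op.generate_layer_model(base)
        peak_planes = {}
        for tag, cfg in [("base", base), ("thick", thick)]:
            vol, truth = op.generate_phantom(cfg)
            nf = op.normalize_decorrelation(vol, layers=truth.layer_model)
            theta = op.estimate_noise_threshold(
                nf, op.vitreous_noise_region(truth.layer_model, vol.shape[2]), 3.0
            )
            vol = op.resolve_projection(nf, vol, theta=theta)
            flat = op.flatten_to_rpe(vol, truth.layer_model)
            ref_flat = ref_layers.shifted(
                flatten_shifts(ref_layers)[0].astype(float)
            )
            nvol = op.normalize_depth(flat.volume, flat.layers, ref_flat)
            prof = op.depth_density_profile(
                nvol, (0.75, 0.35), "m", None, sample_dims_mm=(0.3, 0.5)
            )
            f = op.find_peaks_troughs(prof, min_prominence=0.05)
            peak_planes[tag] = [p.plane for p in f.peaks]
        assert len(peak_planes["base"]) == 3
        assert len(peak_planes["thick"]) == 3
        for a, b in zip(peak_planes["base"], peak_planes["thick"]):
            assert abs(a - b) <= 1

    def test_flow_mass_conserved_under_thickness_scaling(self):
        # nearest-neighbor resampling moves isolated flow sheets without
        # creating or destroying them for moderate thickness ratios
        src = constant_layer_model()
        vol = volume_with_flow(src, [40, 60, 65, 75])
        n0 = int((vol.decorrelation > 0).sum())
        for ratio in (0.7, 1.0, 1.4):
            ref = op.LayerModel({
                k: src.surfaces["ILM"] + (v - src.surfaces["ILM"]) * ratio
                for k, v in src.surfaces.items()
            })
            nvol = op.normalize_depth(vol, src, ref)
            n1 = int((nvol.volume.decorrelation > 0).sum())
            assert abs(n1 - n0) / n0 < 0.05, ratio


class TestNormalizeTransverse:
    def test_identity_landmarks(self):
        layers = constant_layer_model()
        vol = volume_with_flow(layers, [40])
        lm = op.Landmarks(fovea=(0.09, 0.05), disc_center=(0.02, 0.05))
        vol = op.OctaVolume(vol.reflectance, vol.decorrelation, vol.voxel_spacing, lm)
        nvol = op.NormalizedVolume(vol, layers)
        out = op.normalize_transverse(nvol, lm, lm)
        np.testing.assert_array_equal(out.volume.decorrelation, vol.decorrelation)

    def test_disc_fovea_distance_rescaled(self):
        shape = (60, 6, 100)
        layers = constant_layer_model(shape[:2], RPE=90.0)
        refl = np.ones(shape, np.float32)
        deco = np.zeros(shape, np.float32)
        deco[40, :, 50] = 0.5  # feature at x index 40
        src_lm = op.Landmarks(fovea=(0.60, 0.045), disc_center=(0.0, 0.045))
        ref_lm = op.Landmarks(fovea=(0.66, 0.045), disc_center=(0.0, 0.045))
        vol = op.OctaVolume(refl, deco, (15.0, 15.0, 3.1), src_lm)
        out = op.normalize_transverse(op.NormalizedVolume(vol, layers), src_lm, ref_lm)
        xs = np.nonzero(out.volume.decorrelation[:, 3, 50])[0]
        # feature at 0.60 mm maps to 0.66 mm = x index 44 on the reference axis
        assert len(xs) >= 1 and abs(int(xs.mean()) - 44) <= 1
        assert out.volume.landmarks == ref_lm
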