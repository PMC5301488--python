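"""Synthetic phantom generator: geometry, vasculature, rendering."""

import dataclasses

import numpy as np
import pytest

import octapr as op
from octapr.phantom import (
    AreaFractionError,
    LayerParams,
    NoiseParams,
    PhantomConfig,
    PlexusParams,
    ReflectanceParams,
    TailParams,
    noise_free,
    plexus_centerline_separation,
)


class TestLayerModel:
    def test_flat_config_gives_planar_surfaces(self):
        cfg = PhantomConfig.flat_macular(seed=0)
        layers = op.generate_layer_model(cfg)
        for name, surf in layers.surfaces.items():
            assert np.ptp(surf) == pytest.approx(0.0, abs=1e-9), name

    def test_boundary_ordering_holds_everywhere(self):
        layers = op.generate_layer_model(PhantomConfig.maculopapillary(seed=1))
        for upper, lower in zip(op.BOUNDARIES[:-1], op.BOUNDARIES[1:]):
            assert np.all(layers.surface(lower) - layers.surface(upper) >= -1e-9)

    def test_foveal_pit_thins_gcc_by_at_least_50um(self):
        # oracle: evaluate the generated thickness field at the two loci
        cfg = PhantomConfig.maculopapillary(
            seed=0, layer_params=LayerParams(pit_depth_um=100.0)
        )
        layers = op.generate_layer_model(cfg)
        dz = cfg.voxel_spacing[2]
        gcc = layers.thickness("ILM", "IPL/INL") * dz  # µm
        fx, fy = cfg.fovea_center
        dx, dy = cfg.voxel_spacing[0] / 1000, cfg.voxel_spacing[1] / 1000
        at_fovea = gcc[int(round(fx / dx)), int(round(fy / dy))]
        at_15 = gcc[int(round((fx + 1.5) / dx)), int(round(fy / dy))]
        assert at_15 - at_fovea >= 50.0

    def test_nfl_thickens_toward_disc(self):
        cfg = PhantomConfig.maculopapillary(seed=0)
        layers = op.generate_layer_model(cfg)
        nfl = layers.thickness("ILM", "NFL/GCL")
        dxy = (cfg.voxel_spacing[0] / 1000, cfg.voxel_spacing[1] / 1000)
        near = nfl[int(cfg.disc_center[0] / dxy[0]) + 20, int(cfg.disc_center[1] / dxy[1])]
        far = nfl[int((cfg.fovea_center[0] + 2.0) / dxy[0]), int(cfg.fovea_center[1] / dxy[1])]
        assert near > far + 5

    def test_stack_exceeding_grid_is_rejected(self):
        with pytest.raises(Exception, match="stacked layer thickness"):
            op.generate_layer_model(
                PhantomConfig.flat_macular(seed=0, grid_shape=(40, 30, 100))
            )


class TestVasculature:
    def test_no_flow_inside_faz(self, flat_phantom):
        cfg, _, truth = flat_phantom
        nx, ny, _ = cfg.grid_shape
        x = (np.arange(nx)[:, None] + 0.5) * cfg.voxel_spacing[0] / 1000
        y = (np.arange(ny)[None, :] + 0.5) * cfg.voxel_spacing[1] / 1000
        r = np.hypot(x - cfg.fovea_center[0], y - cfg.fovea_center[1])
        inside = r < cfg.faz_radius
        assert not truth.in_situ_flow[inside].any()

    def test_centerline_separation_vanishes_at_merge(self):
        cfg = PhantomConfig.maculopapillary(seed=0, merge_eccentricity=6.5)
        assert plexus_centerline_separation(cfg, 7.0) == 0.0
        assert plexus_centerline_separation(cfg, 6.5) == 0.0
        assert plexus_centerline_separation(cfg, 0.0) > 10

    def test_svp_area_fraction_calibrated_in_gcl_band(self):
        # 3 x 3 mm flat field, target 0.20: en-face flow fraction in the
        # GCL band must land in [0.18, 0.22]
        cfg = PhantomConfig.flat_macular(
            seed=3,
            grid_shape=(200, 200, 176),
            fovea_center=(1.5, 1.5),
            plexus_params={"SVP": PlexusParams(0.20)},
            interconnect_fraction=0.0,
        )
        volume, truth = op.generate_phantom(cfg)
        band = op.resolve_slab(op.standard_plexus_specs()["SVP"], truth.layer_model)
        z = np.arange(cfg.grid_shape[2])
        member = (z >= band[0][..., None]) & (z < band[1][..., None])
        enface_flow = (truth.in_situ_flow & member).any(axis=2)
        # measure away from the FAZ and its dense capillary ring
        nx, ny, _ = cfg.grid_shape
        x = (np.arange(nx)[:, None] + 0.5) * cfg.voxel_spacing[0] / 1000
        y = (np.arange(ny)[None, :] + 0.5) * cfg.voxel_spacing[1] / 1000
        away = np.hypot(x - 1.5, y - 1.5) > cfg.faz_radius + 0.1
        assert 0.18 <= enface_flow[away].mean() <= 0.22

    def test_area_fraction_calibration_within_10pct_over_seeds(self):
        targets = {"SVP": 0.28, "ICP": 0.22, "DCP": 0.13}
        for seed in range(20):
            cfg = PhantomConfig.flat_macular(seed=seed)
            layers = op.generate_layer_model(cfg)
            truth = op.generate_vasculature(cfg, layers)
            for name, target in targets.items():
                assert abs(truth.achieved_fractions[name] - target) <= 0.1 * target

    def test_unreachable_fraction_raises(self):
        cfg = PhantomConfig.flat_macular(
            seed=0,
            plexus_params={"SVP": PlexusParams(0.5, capillary_width_um=8.0,
                                               lobule_mm=0.5)},
        )
        layers = op.generate_layer_model(cfg)
        with pytest.raises(AreaFractionError):
            op.generate_vasculature(cfg, layers)

    def test_labels_lie_in_their_anatomic_bands(self, demo_products):
        truth = demo_products["truth"]
        layers = truth.layer_model
        specs = op.standard_plexus_specs()
        for name, code in [("RPCP", 1), ("SVP", 2), ("ICP", 3), ("DCP", 4)]:
            z_in, z_out = op.resolve_slab(specs[name], layers)
            xs, ys, zs = np.nonzero(truth.plexus_label == code)
            assert len(xs) > 0, name
            assert np.all(zs >= z_in[xs, ys] - 1e-9), name
            assert np.all(zs < z_out[xs, ys]), name


class TestRendering:
    def test_identical_config_and_seed_bit_identical(self):
        cfg = PhantomConfig.flat_macular(seed=5, grid_shape=(60, 40, 140))
        v1, t1 = op.generate_phantom(cfg)
        v2, t2 = op.generate_phantom(cfg)
        assert np.array_equal(v1.reflectance, v2.reflectance)
        assert np.array_equal(v1.decorrelation, v2.decorrelation)
        assert np.array_equal(t1.in_situ_flow, t2.in_situ_flow)
        assert np.array_equal(t1.plexus_label, t2.plexus_label)

    def test_alpha_zero_annihilates_tails(self):
        cfg = noise_free(
            PhantomConfig.flat_macular(
                seed=2,
                grid_shape=(60, 40, 140),
                tail_params=TailParams(alpha_per_mm=0.0),
            )
        )
        volume, truth = op.generate_phantom(cfg)
        off = ~truth.in_situ_flow
        assert float(volume.decorrelation[off].max()) < 1e-6
        assert not truth.artifact_flow.any()

    def test_tail_value_is_source_times_decay_on_uniform_reflectance(self):
        # single flow voxel over uniformly bright tissue: the tail equals
        # contrast * source * alpha^depth exactly
        refl = ReflectanceParams(
            vitreous=1.0, nfl=1.0, gclipl=1.0, inl_top=1.0, inl_bottom=1.0,
            opl=1.0, onl=1.0, rpe=1.0, below=1.0,
        )
        cfg = noise_free(
            PhantomConfig.flat_macular(
                seed=0,
                grid_shape=(8, 6, 140),
                fovea_center=(0.05, 0.04),
                faz_radius=0.0,
                reflectance_params=refl,
                tail_params=TailParams(alpha_per_mm=0.8, reflectance_gate=0.5,
                                       tail_contrast=1.0),
            )
        )
        layers = op.generate_layer_model(cfg)
        in_situ = np.zeros(cfg.grid_shape, dtype=bool)
        z0 = 40
        in_situ[4, 3, z0] = True
        truth = op.PhantomTruth(
            in_situ_flow=in_situ,
            plexus_label=np.zeros(cfg.grid_shape, np.uint8),
            layer_model=layers,
        )
        volume = op.render_volume(cfg, truth)
        src = float(volume.decorrelation[4, 3, z0])
        dz_mm = cfg.voxel_spacing[2] / 1000
        for gap in (1, 10, 40):
            expected = src * 0.8 ** (gap * dz_mm)
            assert volume.decorrelation[4, 3, z0 + gap] == pytest.approx(expected, rel=1e-5)

    def test_artifact_subordinate_to_source_when_noise_free(self):
        cfg = noise_free(PhantomConfig.flat_macular(seed=9, n_trees=1))
        volume, truth = op.generate_phantom(cfg)
        D = volume.decorrelation.astype(float)
        src_running = np.maximum.accumulate(np.where(truth.in_situ_flow, D, 0.0), axis=2)
        art = truth.artifact_flow
        assert art.any()
        assert np.all(D[art] < src_running[art] + 1e-12)

    def test_in_situ_and_artifact_truth_disjoint(self, flat_phantom):
        _, _, truth = flat_phantom
        assert not (truth.in_situ_flow & truth.artifact_flow).any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(Exception):
            PhantomConfig.flat_macular(
                seed=0, plexus_params={"SVP": PlexusParams(1.5)}
            ).validate()
        with pytest.raises(Exception):
            PhantomConfig.flat_macular(seed=0, faz_radius=-0.1).validate()
        with pytest.raises(Exception):
            dataclasses.replace(
                PhantomConfig.flat_macular(seed=0),
                tail_params=TailParams(alpha_per_mm=1.2),
            ).validate()
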