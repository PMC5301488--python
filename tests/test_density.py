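"""Density quantification: vessel mask, depth/cross-section/transverse profiles, CoV."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import octapr as op
from octapr.density import filter_small_components

from conftest import constant_layer_model


def make_nvol(deco, refl=None, landmarks=None):
    shape = deco.shape
    refl = np.ones(shape, np.float32) if refl is None else refl
    vol = op.OctaVolume(refl, deco.astype(np.float32), (15.0, 15.0, 3.1), landmarks)
    layers = constant_layer_model(shape[:2], RPE=float(shape[2] - 2))
    return op.NormalizedVolume(vol, layers)


class TestLargeVesselMask:
    def test_component_of_50_px_removed_51_retained(self):
        mask = np.zeros((60, 60), bool)
        mask[5:10, 5:15] = True  # 5 x 10 = 50 px -> removed
        mask[30:33, 20:37] = True  # 3 x 17 = 51 px -> kept
        out = filter_small_components(mask, min_size=50)
        assert not out[5:10, 5:15].any()
        assert out[30:33, 20:37].all()

    def test_eight_connectivity_joins_diagonals(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:11] = True  # 30 px
        mask[10, 11] = True      # diagonal link
        mask[11:15, 12:18] = True  # 24 px -> joined: 55 px total
        out = filter_small_components(mask, min_size=50)
        assert out.sum() == 55

    def test_all_background_image_gives_empty_mask(self):
        lv = op.build_large_vessel_mask(np.full((80, 80), 0.05))
        assert not lv.mask.any()

    def test_bright_vessel_masked_and_no_small_components_survive(self, rng):
        img = rng.uniform(0, 0.08, (120, 120))
        img[40:46, 10:110] = 0.6  # vessel stripe
        lv = op.build_large_vessel_mask(img)
        assert lv.mask[42, 60]
        labels, n = __import__("scipy.ndimage", fromlist=["label"]).label(
            lv.mask, structure=np.ones((3, 3), int)
        )
        sizes = np.bincount(labels.ravel())[1:]
        assert np.all(sizes > 50)

    def test_physical_scaling_shrinks_window_on_coarse_grids(self):
        img = np.zeros((100, 100))
        img[50, 50] = 30.0
        fine = op.build_large_vessel_mask(img, pixel_size_um=(15.0, 15.0))
        coarse = op.build_large_vessel_mask(img, pixel_size_um=(50.0, 50.0))
        assert coarse.params["min_size"] < 50
        # the coarse-grid smoothing kernel is narrower in pixels
        assert coarse.params["pixel_size_um"] == (50.0, 50.0)
        if fine.mask.any() and coarse.mask.any():
            assert coarse.mask.sum() <= fine.mask.sum()


class TestDepthDensityProfile:
    def test_density_is_flow_fraction(self):
        deco = np.zeros((30, 44, 60))
        # window 0.3 x 0.6 mm at 15 um -> 20 x 40 = 800 px; 80 flow px
        deco[5:25, 2:42, 33][:4, :20] = 0.5
        nvol = make_nvol(deco)
        prof = op.depth_density_profile(
            nvol, (0.225, 0.33), "t", None, sample_dims_mm=(0.3, 0.6)
        )
        assert prof.n_pixels[0] == 800
        assert prof.density[33] == pytest.approx(0.10)
        assert prof.density[10] == 0.0

    def test_fully_masked_window_flagged_absent(self):
        deco = np.zeros((30, 60, 60))
        nvol = make_nvol(deco)
        lv = op.LargeVesselMask(np.ones((30, 60), bool))
        prof = op.depth_density_profile(nvol, (0.225, 0.45), "t", lv)
        assert prof.absent.all()
        assert np.isnan(prof.density).all()

    def test_window_outside_grid_rejected(self):
        nvol = make_nvol(np.zeros((30, 60, 60)))
        with pytest.raises(ValueError, match="outside grid"):
            op.depth_density_profile(nvol, (10.0, 0.45), "t", None)

    def test_adding_flow_never_lowers_density(self, rng):
        deco = (rng.uniform(0, 1, (30, 60, 60)) > 0.9) * 0.5
        nvol = make_nvol(deco)
        p1 = op.depth_density_profile(nvol, (0.225, 0.45), "t", None)
        deco2 = deco.copy()
        deco2[10, 10, :] = 0.5
        p2 = op.depth_density_profile(make_nvol(deco2), (0.225, 0.45), "t", None)
        assert np.all(p2.density >= p1.density - 1e-12)


class TestCrossSectionMap:
    def test_zero_flow_gives_zero_map(self):
        vol = op.OctaVolume(
            np.ones((60, 56, 64), np.float32), np.zeros((60, 56, 64), np.float32),
            (15.0, 15.0, 3.1),
        )
        m = op.cross_section_density_map(vol)
        assert m.density.shape[0] > 0 and np.all(m.density == 0)

    def test_uniform_random_flow_recovers_rate(self, rng):
        deco = (rng.uniform(0, 1, (60, 56, 64)) < 0.10) * 0.5
        vol = op.OctaVolume(
            np.ones((60, 56, 64), np.float32), deco.astype(np.float32),
            (15.0, 15.0, 3.1),
        )
        m = op.cross_section_density_map(vol)
        # each super-voxel holds ~6 x 53 x 3 voxels; 4 sigma binomial slack
        n = 6 * 53 * 3
        tol = 4 * np.sqrt(0.1 * 0.9 / n)
        assert np.abs(m.density - 0.10).max() < tol + 0.02
        assert m.density.mean() == pytest.approx(0.10, abs=0.005)

    def test_phantom_shows_three_bands_merging_peripherally(self, demo_products):
        nvol = demo_products["nvol"]
        truth = demo_products["truth"]
        cfg = demo_products["config"]
        m = op.cross_section_density_map(nvol.volume)
        xc = 0.5 * (m.x_edges_mm[:-1] + m.x_edges_mm[1:])
        fx = cfg.fovea_center[0]
        dz_mm = nvol.volume.voxel_spacing[2] / 1000.0
        dx_mm = nvol.volume.voxel_spacing[0] / 1000.0
        ilm = nvol.layers.surface("ILM")

        def bands(x_mm):
            # average 0.5 mm of columns below the local ILM; a plexus sheet
            # fills ~1/3 of the 10 µm super-voxel and may straddle two
            # z-bins, so the band cut sits at 0.015
            sel = np.abs(xc - x_mm) < 0.25
            col = m.density[sel].mean(axis=0)
            ix = np.abs(np.arange(ilm.shape[0]) * dx_mm - x_mm) < 0.25
            ilm_bin = int(ilm[ix].min() * dz_mm / m.supervoxel_mm[2])
            hot = np.nonzero(col > 0.015)[0]
            hot = hot[hot > ilm_bin]
            return np.split(hot, np.nonzero(np.diff(hot) > 1)[0] + 1) if len(hot) else []

        assert len(bands(fx + 1.5)) >= 3  # SVP + ICP + DCP distinct
        assert len(bands(fx + 7.2)) <= 2  # SVP + merged ICP/DCP


class TestTransverseProfile:
    def test_avascular_slab_is_zero_and_vessel_window_is_one(self):
        shape = (120, 56, 64)
        deco = np.zeros(shape, np.float32)
        deco[:, :, 30] = 0.5  # full-thickness flow at the SVP-ish plane
        refl = np.ones(shape, np.float32)
        lm = op.Landmarks(fovea=(1.2, 0.42), disc_center=(0.1, 0.42), disc_radius=0.05)
        vol = op.OctaVolume(refl, deco, (15.0, 15.0, 3.1), lm)
        layers = constant_layer_model(shape[:2], RPE=60.0)
        specs = op.standard_plexus_specs()
        prof = op.transverse_density_profile(
            vol, {"SVP": specs["SVP"], "DCP": specs["DCP"]}, layers
        )
        assert np.all(prof.densities["SVP"] == 1.0)  # plane 30 in SVP band
        assert np.all(prof.densities["DCP"] == 0.0)  # avascular band

    def test_rpcp_density_decays_from_disc(self, demo_products):
        nvol = demo_products["nvol"]
        specs = op.standard_plexus_specs()
        prof = op.transverse_density_profile(
            nvol.volume, {"RPCP": specs["RPCP"]}, nvol.layers
        )
        sel = prof.positions_mm <= 2.3  # RPCP territory
        x = prof.positions_mm[sel]
        # 5-step moving average: the trend, not single-window shot noise
        d = np.convolve(prof.densities["RPCP"][sel], np.ones(5) / 5, mode="valid")
        rho = spearmanr(x[2:-2], d).statistic
        assert rho < -0.9


class TestRepeatability:
    def test_constant_measurements_have_zero_cov(self):
        assert op.repeatability_cov([0.30, 0.30, 0.30]) == 0.0

    def test_two_point_closed_form(self):
        # SD([0.2, 0.3]) / mean = 0.0707107 / 0.25
        assert op.repeatability_cov([0.2, 0.3]) == pytest.approx(28.2842712, abs=1e-6)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.1, 0.5, 6)
        assert op.repeatability_cov(vals * 7.3) == pytest.approx(
            op.repeatability_cov(vals), rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            op.repeatability_cov([0.3])
        with pytest.raises(ValueError):
            op.repeatability_cov([0.0, 0.0])
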