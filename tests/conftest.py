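"""Shared fixtures: phantoms and the standard resolve/normalize chain.

Session-scoped phantoms keep the suite fast: generation is deterministic,
so sharing them between tests cannot couple test outcomes.
"""

from __future__ import annotations

import numpy as np
import pytest

import octapr as op


def run_standard(cfg, theta_multiplier: float = 3.0):
    """Generate a phantom and run resolve -> flatten/normalize -> mask.

    Returns a dict with every intermediate the tests may want.
    """
    volume, truth = op.generate_phantom(cfg)
    normflow = op.normalize_decorrelation(volume, layers=truth.layer_model)
    theta = op.estimate_noise_threshold(
        normflow,
        op.vitreous_noise_region(truth.layer_model, volume.shape[2]),
        theta_multiplier,
    )
    resolved = op.resolve_projection(normflow, volume)
    nvol = op.normalize_volume(resolved, truth.layer_model)
    svp_band = op.resolve_slab(op.standard_plexus_specs()["SVP"], nvol.layers)
    lvmask = op.build_large_vessel_mask(
        op.project_flow_max(nvol.volume, svp_band, "SVP").data,
        pixel_size_um=cfg.voxel_spacing[:2],
    )
    return {
        "config": cfg,
        "volume": volume,
        "truth": truth,
        "normflow": normflow,
        "theta": theta,
        "resolved": resolved,
        "nvol": nvol,
        "lvmask": lvmask,
    }


@pytest.fixture(scope="session")
def flat_phantom():
    """Flat-layer macular phantom (no pit, no disc, no large vessels)."""
    cfg = op.PhantomConfig.flat_macular(seed=7)
    volume, truth = op.generate_phantom(cfg)
    return cfg, volume, truth

@pytest.fixture(scope="session")
def demo_products():
    """Full standard chain on the maculopapillary demo phantom."""
    return run_standard(op.PhantomConfig.maculopapillary(seed=0))


@pytest.fixture(scope="session")
def flat_products():
    """Full standard chain on a flat phantom with one large-vessel tree."""
    return run_standard(op.PhantomConfig.flat_macular(seed=7, n_trees=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_layer_model(shape=(8, 6), **depths):
    """LayerModel with spatially constant surfaces (test geometry)."""
    defaults = {
        "ILM": 20.0, "NFL/GCL": 28.0, "IPL/INL": 57.0,
        "INL/OPL": 72.0, "OPL/ONL": 82.0, "RPE": 120.0,
    }
    defaults.update(depths)
    return op.LayerModel({k: np.full(shape, v) for k, v in defaults.items()})
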