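"""Depth-resolved capillary density profiles and plexus detection.

After projection resolution the volume is flattened to the RPE and
depth-normalized; capillary density is counted per depth plane in
0.1 x 0.8 mm sample areas (large vessels masked out), and profile peaks
are assigned to plexuses by the anatomic band containing their depth.
"""

import numpy as np

import octapr as op

config = op.PhantomConfig.maculopapillary(seed=0)
volume, truth = op.generate_phantom(config)
normflow = op.normalize_decorrelation(volume, layers=truth.layer_model)
theta = op.estimate_noise_threshold(
    normflow, op.vitreous_noise_region(truth.layer_model, volume.shape[2]), 3.0
)
resolved = op.resolve_projection(normflow, volume)
nvol = op.normalize_volume(resolved, truth.layer_model)

svp_band = op.resolve_slab(op.standard_plexus_specs()["SVP"], nvol.layers)
lvmask = op.build_large_vessel_mask(
    op.project_flow_max(nvol.volume, svp_band, "SVP").data,
    pixel_size_um=config.voxel_spacing[:2],
)

fx, fy = config.fovea_center
regions = {
    "peripapillary": config.landmarks().disc_edge_x + 0.25,
    "parafoveal": fx + 1.5,
    "perifoveal": fx + 2.5,
    "peripheral": fx + 7.0,
}
for region, x_center in regions.items():
    windows = [
        op.depth_density_profile(nvol, (x_center + off, fy), region, lvmask)
        for off in (-0.2, -0.1, 0.0, 0.1, 0.2)
    ]
    prof = op.mean_profile(windows, region)
    findings = op.assign_plexus_labels(
        op.find_peaks_troughs(prof), nvol.layers, region
    )
    peaks = [
        f"{p.label}@plane {p.plane} (density {p.height:.3f})"
        for p in findings.peaks if p.label != "unassigned"
    ]
    print(f"{region:13s}: " + "; ".join(peaks))
print("-> each density is the flow-pixel fraction at that depth plane;")
print("   macular regions separate SVP/ICP/DCP, the periphery shows the")
print("   merged deep complex, and the peripapillary NFL adds the RPCP.")
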