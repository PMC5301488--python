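"""Locate the eccentricity where the ICP and DCP merge into one plexus.

The generator separates the two deep plexuses by the local INL thickness,
shrinking linearly to zero at a configurable eccentricity (6.5 mm here).
Depth profiles every 0.5 mm along the temporal axis count the peaks in the
deep vascular complex band; the merge locus is the innermost eccentricity
beyond which a single peak remains.
"""

import numpy as np

import octapr as op

config = op.PhantomConfig.merge_study(seed=1, merge_eccentricity=6.5)
volume, truth = op.generate_phantom(config)
normflow = op.normalize_decorrelation(volume, layers=truth.layer_model)
op.estimate_noise_threshold(
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
findings = []
for ecc in np.arange(3.0, 8.1, 0.5):
    profs = [
        op.depth_density_profile(nvol, (fx + ecc + off, fy), "scan", lvmask)
        for off in (-0.1, 0.0, 0.1)
    ]
    f = op.assign_plexus_labels(
        op.find_peaks_troughs(op.mean_profile(profs)), nvol.layers, "scan"
    )
    findings.append(f)
    print(f"eccentricity {ecc:.1f} mm: {f.dvc_peak_count} deep-complex peak(s)")

estimate, stable = op.estimate_merge_eccentricity(findings)
print(f"estimated merge eccentricity: {estimate} mm (stable={stable})")
print(f"generator truth: {config.merge_eccentricity} mm")
print("-> the last ~0.5 mm of separation is below the 3.1 um axial voxel")
print("   resolution, so the detector reports the merge one step early.")
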