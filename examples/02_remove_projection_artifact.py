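"""Remove flow-projection artifact with the PR rule and score it vs truth.

A voxel is kept as in-situ flow only if its reflectance-normalized
decorrelation exceeds every shallower voxel of the same A-scan (and the
noise threshold); everything else is zeroed.  With the phantom's ground
truth we can score exactly how much artifact was removed and how much real
flow survived.
"""

import octapr as op

config = op.PhantomConfig.maculopapillary(seed=0)
volume, truth = op.generate_phantom(config)

normflow = op.normalize_decorrelation(volume, layers=truth.layer_model)
noise_band = op.vitreous_noise_region(truth.layer_model, volume.shape[2])
theta = op.estimate_noise_threshold(normflow, noise_band, multiplier=3.0)
print(f"reference reflectance {normflow.r_ref:.3f}, noise threshold {theta:.4f}")

resolved = op.resolve_projection(normflow, volume)
kept = resolved.decorrelation > 0

art = float(kept[truth.artifact_flow].mean())
ins = float(kept[truth.in_situ_flow].mean())
print(f"artifact-only voxels surviving: {100 * art:.2f}%  (ideal 0%)")
print(f"in-situ flow voxels retained:   {100 * ins:.2f}%  (ideal 100%)")
print("-> residual artifact sits immediately below strong vessels where the")
print("   tail is nearly as strong as its source; deeper tails are removed.")
print("-> much of the in-situ loss is inside multi-voxel vessel trunks and")
print("   vertical interconnects, where only the strongest voxel of a stack")
print("   can win the per-A-scan comparison; single-voxel capillary sheets")
print("   retain far better:")

cap = truth.in_situ_flow & (truth.plexus_label == 4)  # DCP, deepest plexus
print(f"deep capillary plexus retention: {100 * float(kept[cap].mean()):.1f}%")
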