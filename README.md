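# octapr — projection-resolved OCT angiography analysis

OCT angiography (OCTA) images retinal blood flow by the decorrelation of
repeated OCT scans, but superficial vessels cast flickering shadows onto
deeper tissue: every vessel acquires a "tail" of spurious flow signal, so
deeper capillary plexuses cannot be imaged cleanly and the normally
avascular outer retina appears perfused.  `octapr` implements the
projection-resolved (PR-OCTA) analysis chain for people who want to study
depth-resolved retinal vascular anatomy — and to test such algorithms
quantitatively, it ships a volumetric retinal phantom generator with
per-voxel ground truth, so every stage can be scored against a known
answer without any image download.

## The algorithm

Let `D(x, y, z) ∈ [0, 1]` be the SSADA-scale decorrelation and `R(x, y, z)`
the reflectance of an OCTA volume, with `z` increasing from the vitreous
downward.  The reflectance-normalized decorrelation is

    D̄ = D / max(R / R_ref, ε),          R_ref = median inner-retina reflectance

and a noise threshold `θ = mean + k·SD` of `D̄` in an avascular region
separates flow from background.  The projection-resolution rule keeps a
voxel as in-situ flow iff

    D̄(x, y, z) ≥ θ   and   D̄(x, y, z) > max{ D̄(x, y, z′) : z′ < z },

i.e. only where the normalized signal strictly exceeds *every* shallower
voxel of the same axial scan; all other signal is zeroed.  A projection
tail rides on tissue reflectance, so normalization pins it below its
(shallower) source and the rule removes it, while genuine deeper flow —
typically hosted in darker tissue — survives.  The retained values of each
A-scan strictly increase with depth, which also makes the operation
idempotent.

On the cleaned volume the package segments the vasculature into four
plexuses by fractional anatomic boundaries — RPCP (ILM → NFL/GCL), SVP
(NFL/GCL → inner 80% of the ganglion cell complex), ICP (outer 20% of the
GCC → inner 50% of the INL), DCP (outer 50% of the INL → outer OPL) — and
quantifies capillary density three ways: depth-resolved profiles in
0.1 × 0.8 mm sample areas (large vessels masked by smoothing the SVP
en-face angiogram, thresholding at decorrelation 0.12 and keeping
components > 50 px), cross-sectional maps over 0.1 × 0.8 × 0.01 mm
super-voxels, and per-plexus transverse profiles sampled every 0.05 mm
from the optic disc edge.  Profile peaks are assigned to plexuses by the
anatomic band containing their depth, and the eccentricity where the deep
vascular complex first holds a single peak estimates the ICP/DCP merge
locus.

## Worked example

`examples/` holds one short script per capability.  Removing projection
artifact from a phantom with known truth
(`python examples/02_remove_projection_artifact.py`):

```
reference reflectance 0.932, noise threshold 0.1301
artifact-only voxels surviving: 0.36%  (ideal 0%)
in-situ flow voxels retained:   72.62%  (ideal 100%)
deep capillary plexus retention: 88.4%
```

Of ~1.6 million artifact-only tail voxels, 0.36% survive (they sit
immediately below strong vessels, where a tail is nearly as strong as its
source); the in-situ losses concentrate in multi-voxel vessel trunks where
only the strongest voxel of a stack can win the per-A-scan comparison.
Depth profiling and plexus detection on the same phantom
(`python examples/03_depth_density_profiles.py`):

```
parafoveal   : SVP@plane 61 (density 0.148); ICP@plane 81 (density 0.274); DCP@plane 93 (density 0.144)
peripheral   : SVP@plane 61 (density 0.107); ICP/DCP@plane 87 (density 0.354)
```

Macular profiles separate the three plexuses at their generated depths;
peripherally the ICP and DCP appear as one merged peak whose density
exceeds the SVP's.  Each density is the flow-pixel fraction at that depth
plane within the sample area.  `python examples/04_merge_eccentricity.py`
scans profiles every 0.5 mm and recovers a 6.5 mm configured merge locus
as 6.0 mm — the final half-millimetre of plexus separation is below the
3.1 µm axial voxel.

The same chain is available as a CLI for shell use:

```bash
octapr demo --out demo_run --seed 0          # full pipeline + report
octapr simulate --out phantom.h5 --seed 1    # phantom + ground truth
octapr resolve --in phantom.h5 --out pr.h5   # projection resolution
```

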