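# Methods

This note records the models, parameter choices and numerical conventions
behind `octapr`, in the order the pipeline applies them.

## Coordinate and data conventions

Grids are `(nx, ny, nz)` with the depth index `z = 0` at the vitreous side;
"shallower" always means smaller `z`.  Transverse positions are in mm from
the grid origin with +x pointing temporally (the optic disc sits at smaller
x than the fovea).  Decorrelation `D` is the SSADA-scale flow signal in
[0, 1]; reflectance `R` is nonnegative in arbitrary units.  Depth bands are
half-open `[z_in, z_out)` in voxel index, so the four plexus slabs form an
exact partition of the inner retina — a closed/open convention the slab
algebra tests rely on.

## Synthetic phantom

The generator emulates a 70 kHz spectral-domain OCT acquisition: 3.1 µm
axial voxels with 512 available planes, and 15 µm-class transverse
sampling.  Three canned geometries cover the use cases:

* `maculopapillary()` — 256 × 64 × 256 at (50, 15, 3.1) µm: a single
  12.8 × 0.96 mm strip spanning the optic disc through ~7.5 mm temporal to
  the fovea, so all four sampling regions and the ICP/DCP merge locus fit
  in one volume.  The coarse x-pitch is the price of the field of view at
  desk scale; the full 304 × 304 × 512 geometry is supported but not needed
  by any test.
* `flat_macular()` — 220 × 80 × 176 at (15, 15, 3.1) µm with flat layers
  (no pit, no NFL gain, disc outside the grid): the calibration workhorse,
  where generated area fractions can be compared against measured
  densities without geometric confounds.  No large-vessel trees by
  default, so density recovery is not confounded by mask-edge selection.
* `merge_study()` — 360 × 64 × 176 at (25, 15, 3.1) µm, flat layers, no
  vessels: a 9 mm strip for merge-locus estimation.

**Layers.**  Boundaries are built downward from a flat ILM with base
thicknesses (µm): NFL 25, GCL+IPL 90, INL 48, OPL 30, outer retina to the
RPE 120, under 60 µm of vitreous.  The foveal pit removes `pit_depth_um`
(default 160) of inner-retina thickness with a Gaussian transverse profile
(σ 0.35 mm), scaling all inner layers proportionally; peripapillary NFL
thickening adds up to 70 µm with σ 1.0 mm around the disc.  All
modulations are Gaussian, hence band-limited and smooth.  A stack that
would leave the grid is rejected at config validation.

**Vasculature.**  Capillary beds are Voronoi-ridge skeletons of
jittered-grid (blue-noise) seed points — the lobular, directionless look of
the deep plexuses — dilated to width by thresholding the anisotropy-aware
distance transform at the exact quantile that realizes the target area
fraction inside a calibration region.  Achieved fractions therefore match
their targets to a pixel; the mesh scale (lobule size) defaults to the
value that puts the bare skeleton at ~55% of the target, and a target that
would need dilation beyond twice the capillary width raises
`AreaFractionError` rather than silently clipping.  The RPCP is drawn as
arcuate streamlines radiating from the disc edge, accumulated one spoke at
a time until a 0.5 mm annulus outside the disc reaches the target
fraction; spokes terminate at random lengths up to 2.5 mm, so density
decays outward as the histology describes.  The SVP additionally carries
branching large-vessel trunks (100 µm wide, decorrelation 0.45–0.65)
rasterized as wandering polylines.  A foveal avascular zone of radius
0.3 mm is carved from every plexus and bounded by a one-capillary-wide
ring; the ring is deliberately excluded from the area-fraction calibration
region so its local density does not dilute the mesh elsewhere.  Vertical
interconnecting segments join the SVP to the deep plexuses at 0.8% of
columns.

Plexus depths: RPCP at mid-NFL, SVP at the middle of its slab, and the
ICP/DCP centerlines inside the INL, hugging its inner/outer borders at the
fovea and converging linearly to mid-INL at `merge_eccentricity` (default
6.5 mm).  Centerlines are clamped half a voxel inside their half-open host
bands so every labeled truth voxel verifiably lies in its anatomic band,
merged or not.  Capillaries are one voxel thick axially (their ~8 µm
diameter is below the 20 µm SSADA axial resolution anyway); trees are
three voxels thick.

**Rendering.**  Reflectance is a per-layer base level — NFL 1.2, GCL+IPL
0.95, INL graded 0.62 → 0.42 with depth, OPL 0.85, ONL 0.35, RPE 1.6,
vitreous 0.05 — times multiplicative speckle (clipped normal, contrast
0.2).  The INL gradient matters: it is what gives deeper in-situ flow the
reflectance advantage that lets it survive projection resolution, mirroring
the real contrast between the dark nuclear layer and the bright plexiform
layers.  In-situ capillary decorrelation is drawn U(0.20, 0.40) and large
vessels U(0.45, 0.65): capillaries sit above the 0.12 large-vessel
threshold scale but clearly below arteries/veins, and — importantly for the
vessel mask — the *smoothed* en-face capillary background
(fraction × mean ≈ 0.28 × 0.30 ≈ 0.08) stays safely under the 0.12 cut.

**Projection tails.**  Under every in-situ voxel at depth `z0`:

    D_tail(z) = c · D_src · α^((z − z0)·dz_mm) · min(R̄(z), R̄(z0)) / R̄(z0)

on voxels whose base reflectance exceeds the gate (0.38, i.e. the
plexiform layers and the RPE complex but not the dark ONL), with
attenuation `α = 0.8` per mm and shadow contrast `c = 0.85` (a flickering
shadow is dimmer than the flow that casts it).  `R̄` is the *mean* (pre-
speckle) tissue reflectance: decorrelation is a normalized statistic, so
per-voxel speckle amplitude largely divides out of the tail.  Two
consequences are provable and tested: the tail's decorrelation is strictly
below its source's (`c·α^Δ < 1`), and its reflectance-normalized
decorrelation is too — so in the noise-free limit the PR rule removes
every artifact voxel exactly.  With noise on, survivors concentrate in the
first voxels under strong vessels where the margin `1 − c·α^Δ` is small;
at the defaults this residual is ~0.3% of tail voxels, a realistic
imperfection.  `α = 0` is accepted as the degenerate shadow-free phantom.
Background decorrelation noise is half-normal with σ 0.005.

An option renders in-situ values as a per-A-scan ladder of strictly
increasing normalized decorrelation — the constructed best case in which
projection resolution provably retains 100% of real flow; it is used to
separate rule-induced losses from phantom-physics losses.

## Projection resolution

Normalization divides `D` by `max(R_s / R_ref, ε)` with `ε = 0.1` and
`R_ref` the median reflectance over the inner retina [ILM, OPL/ONL).
`R_s` is the reflectance smoothed *transversely* (Gaussian σ 2 px):
dividing by raw speckle would inject ±20% noise into every D̄ comparison,
while smoothing along depth could locally invert the shallower-vs-deeper
ordering the rule depends on; transverse-only smoothing is exact for
laterally homogeneous layers.  The noise threshold is mean + k·SD of D̄ in
an avascular region.  The vitreous is the pipeline default region — unlike
the conventional ONL choice it provably contains no projection tails
(shadows fall only *below* their sources), and being the darkest
compartment it yields the most conservative cut.  `k = 2.33` (the Gaussian
99th percentile) is the function default; the pipeline uses `k = 3.0`
because the phantom's noise floor is one-sided (half-normal), where 2.33
passes ~3% of voxels and would seed a visible vitreous baseline in the
density profiles.

Tie-breaking is strict: equality with the running maximum classifies a
voxel as artifact (a shadow can at most replicate its source), and the
first suprathreshold voxel of an A-scan is always retained (the maximum
over the empty set is −∞).  The production implementation uses a shifted
cumulative maximum; a deliberately naive reference implementation re-scans
all shallower voxels per depth plane and the two must agree exactly on
random volumes.

## Registration and depth normalization

Volumes are flattened by integer per-column shifts that align the rounded
RPE at its deepest position (nonnegative shifts, vitreous-side zero
padding, idempotent).  Depth is then resampled so each structural layer
group (ILM+NFL, GCL+IPL, INL, OPL, and the outer retina) matches a
reference subject's thickness, via a per-column monotone piecewise-linear
map with control points at the anatomic boundaries and rigid extensions
above the ILM and below the RPE.  Reflectance is interpolated linearly.
Flow takes the *maximum* over the source voxels spanned by each output
voxel (nearest voxel where the span is empty): plain nearest-neighbor
point-sampling would skip alternate source planes wherever a layer is
compressed and silently delete thin flow sheets, while linear interpolation
would smear flow across the noise threshold.  The span-maximum degenerates
to nearest-neighbor at unit scaling and preserves flow-voxel counts within
a few percent for thickness ratios in [0.7, 1.4].  Columns whose source
layer is near zero-thickness where the reference is not are flagged and
excluded from profiling.  The transverse axis is registered by the affine
map sending the subject's disc and fovea centers onto the reference's.

## Density quantification

Depth profiles count suprathreshold flow pixels per plane inside
0.1 × 0.8 mm windows, excluding pixels under the large-vessel mask from
numerator and denominator alike; fully masked windows are flagged absent
rather than zero.  The large-vessel mask smooths the SVP en-face maximum
projection with a Gaussian (20 × 20 px window; the window prescribes no σ,
so σ = window/4 truncated at the window support), thresholds at
decorrelation 0.12, and keeps 8-connected components strictly larger than
50 px.  Those pixel units are referenced to a 15 µm pitch; on coarser
grids the pipeline rescales the window per axis and the component cut by
pixel area so the mask keeps its physical footprint (a 20 px window at
50 µm pixels would otherwise be a 1 mm smoother and swallow the field).

Because a 0.1 × 0.8 mm window over a capillary mesh sees only a handful of
lobule walls, a single window's density has ~10% relative sampling noise.
Region profiles therefore average several windows — five x-offset windows
per region in the pipeline, 24 tiled windows in the calibration
experiments — mirroring the population averaging behind reported density
profiles.  Peaks are detected by prominence (default 0.02 density — above
the phantom noise floor, below the smallest plexus peak) and labeled by
the anatomic band containing their depth; in the peripheral region a lone
deep-complex peak is labeled as the merged ICP/DCP.  The merge locus is
the innermost eccentricity beyond which every profile holds one
deep-complex peak; a non-monotone peak-count sequence reports the last
transition and flags instability.  Cross-sectional maps tile the section
with 0.1 × 0.8 × 0.01 mm super-voxels (flow-voxel fraction each);
transverse profiles use per-plexus full-thickness maximum projections in a
0.7 mm swath every 0.05 mm from the disc edge, large vessels included.
Repeatability is the coefficient of variation (sample SD / mean, percent).

## What the phantom does and does not establish

The phantom reproduces the *mechanisms* the pipeline must handle — layered
anatomy with realistic reflectance contrast, plexuses at
histology-consistent depths, reflectance-gated exponential tails, speckle
and a noise floor — with every flow voxel labeled, which is exactly what
real data cannot provide.  It does not simulate wave optics or speckle
statistics of SSADA processing, eye motion, vessel pulsatility, pathology,
or the choroid (the volume below the RPE is homogeneous tissue), and its
capillary geometry (width, lobule scale) is plausible rather than
measured.  Passing the suite therefore demonstrates algorithmic
correctness and quantitative recovery under known ground truth, not
clinical performance.  Two resolution limits are inherent and visible in
the numbers: the last ~0.5 mm of ICP/DCP separation is below the 3.1 µm
axial voxel, so a 6.5 mm merge locus is reported at 6.0 mm; and within
multi-voxel vessel trunks only the strongest voxel of a stack can satisfy
the strictly-increasing rule, so whole-vessel retention is structurally
below 100% even though single-voxel capillary sheets retain at 95–100%.
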