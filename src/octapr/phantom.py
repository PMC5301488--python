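"""Synthetic OCTA phantom: layered retina, four plexuses, projection tails.

The generator emulates a 70 kHz SD-OCT acquisition geometry (3.1 µm axial
voxels, 15 µm-class transverse sampling) over a retina with a foveal pit,
peripapillary NFL thickening, and four vascular plexuses at their
histology-consistent depths:

* RPCP — radial, arcuate capillary segments in the NFL near the optic disc,
* SVP  — branching large-vessel trees plus an isotropic capillary mesh in
  the GCL band,
* ICP / DCP — lobular capillary meshes at the inner and outer INL borders
  whose depth separation shrinks linearly with eccentricity and vanishes at
  a configurable merge eccentricity,

plus vertical interconnecting segments, a foveal avascular zone bounded by a
capillary ring, and a flow-projection tail under every flow voxel.  Every
voxel of generated ("in-situ") flow and every artifact-only voxel is
recorded in a :class:`PhantomTruth`, the ground-truth oracle for the
downstream stages.

Capillary meshes are Voronoi-ridge skeletons of blue-noise (jittered-grid)
seed points, dilated to width by thresholding the Euclidean distance
transform at the exact quantile that realizes the target area fraction, so
achieved fractions match their targets to within a pixel.

The projection tail under an in-situ flow voxel at depth ``z0`` is

    D_tail(z) = D_src * alpha**((z - z0) * dz_mm) * min(R(z), R(z0)) / R(z0)

on voxels whose reflectance exceeds the gate: the shadow decays
exponentially with depth and scales with the reflectance of the tissue it
flickers on (capped at the source's own level).  Consequently the tail's
reflectance-normalized decorrelation is strictly below its source's, which
is what makes the artifact removable by the projection-resolution rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .core import BOUNDARIES, Landmarks, LayerError, LayerModel, OctaVolume

PLEXUS_LABELS = {"none": 0, "RPCP": 1, "SVP": 2, "ICP": 3, "DCP": 4, "interconnect": 5}
LABEL_NAMES = {v: k for k, v in PLEXUS_LABELS.items()}


class AreaFractionError(ValueError):
    """Target capillary area fraction unreachable at the given width."""


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LayerParams:
    """Layer thicknesses (µm) and their transverse modulation.

    The foveal pit removes ``pit_depth_um`` of inner-retina thickness at the
    fovea center with a Gaussian transverse profile; peripapillary NFL
    thickening adds up to ``nfl_peak_gain_um`` near the disc.
    """

    vitreous_um: float = 60.0
    nfl_um: float = 25.0
    gclipl_um: float = 90.0
    inl_um: float = 48.0
    opl_um: float = 30.0
    onl_um: float = 120.0
    pit_depth_um: float = 160.0
    pit_sigma_mm: float = 0.35
    nfl_peak_gain_um: float = 70.0
    nfl_gain_sigma_mm: float = 1.0

    @property
    def inner_total_um(self) -> float:
        return self.nfl_um + self.gclipl_um + self.inl_um + self.opl_um


@dataclass(frozen=True)
class PlexusParams:
    """Per-plexus synthesis parameters.

    ``area_fraction`` is the capillary (not large-vessel) en-face area
    fraction target; ``lobule_mm`` fixes the Voronoi mesh scale (None =
    derived from the target so the undilated skeleton sits below it).
    """

    area_fraction: float
    capillary_width_um: float = 18.0
    lobule_mm: float | None = None
    pattern: str = "lobular"  # {"radial", "mesh+trees", "lobular"}


@dataclass(frozen=True)
class TailParams:
    """Projection-tail model.

    The shadow under a flow voxel starts at ``tail_contrast`` times the
    source decorrelation (a flickering shadow is dimmer than the flow that
    casts it), decays exponentially with depth at ``alpha_per_mm``, and is
    visible only on sufficiently bright tissue (``reflectance_gate`` — in
    practice the plexiform layers and the RPE complex, not the dark ONL).
    """

    alpha_per_mm: float = 0.8
    reflectance_gate: float = 0.38
    tail_contrast: float = 0.85


@dataclass(frozen=True)
class NoiseParams:
    speckle_contrast: float = 0.2
    decorrelation_noise: float = 0.005


@dataclass(frozen=True)
class ReflectanceParams:
    """Per-layer reflectance levels (arbitrary units)."""

    vitreous: float = 0.05
    nfl: float = 1.2
    gclipl: float = 0.95
    inl_top: float = 0.62
    inl_bottom: float = 0.42
    opl: float = 0.85
    onl: float = 0.35
    rpe: float = 1.6
    below: float = 0.45
    rpe_band_um: float = 15.0


_DEFAULT_PLEXUS = {
    "RPCP": PlexusParams(0.30, pattern="radial"),
    "SVP": PlexusParams(0.28, pattern="mesh+trees"),
    "ICP": PlexusParams(0.22),
    "DCP": PlexusParams(0.13),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Everything the generator needs, including the random seed."""

    grid_shape: tuple[int, int, int] = (256, 64, 256)
    voxel_spacing: tuple[float, float, float] = (50.0, 15.0, 3.1)  # µm
    fovea_center: tuple[float, float] = (5.3, 0.48)  # mm, grid coords
    disc_center: tuple[float, float] = (1.3, 0.48)
    disc_radius: float = 0.75
    layer_params: LayerParams = field(default_factory=LayerParams)
    plexus_params: dict[str, PlexusParams] = field(
        default_factory=lambda: dict(_DEFAULT_PLEXUS)
    )
    reflectance_params: ReflectanceParams = field(default_factory=ReflectanceParams)
    faz_radius: float = 0.30  # mm
    merge_eccentricity: float = 6.5  # mm, ICP/DCP coalescence
    rpcp_extent_mm: float = 2.5  # max reach of radial capillaries from disc edge
    interconnect_fraction: float = 0.008
    n_trees: int = 1
    tree_width_um: float = 100.0
    # SSADA-scale decorrelation of flow voxels: capillaries sit above the
    # 0.12 large-vessel threshold but below arteries/veins (faster flow)
    capillary_flow_range: tuple[float, float] = (0.20, 0.40)
    vessel_flow_range: tuple[float, float] = (0.45, 0.65)
    tail_params: TailParams = field(default_factory=TailParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigError("voxel spacing must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigError("grid shape must be positive")
        lp = self.layer_params
        stack = lp.vitreous_um + lp.nfl_um + lp.gclipl_um + lp.inl_um + lp.opl_um + lp.onl_um
        stack += lp.nfl_peak_gain_um
        if self.grid_shape[2] * self.voxel_spacing[2] <= stack:
            raise ConfigError(
                f"axial extent {self.grid_shape[2] * self.voxel_spacing[2]:.0f} µm "
                f"does not exceed the stacked layer thickness {stack:.0f} µm"
            )
        for name, p in self.plexus_params.items():
            if not 0.0 < p.area_fraction < 1.0:
                raise ConfigError(f"{name} area fraction must be in (0, 1)")
        if self.faz_radius < 0:
            raise ConfigError("faz_radius must be >= 0")
        if not 0.0 <= self.tail_params.alpha_per_mm < 1.0:
            # alpha = 0 is the degenerate shadow-free phantom
            raise ConfigError("tail attenuation alpha must be in [0, 1)")
        if self.merge_eccentricity <= 0:
            raise ConfigError("merge_eccentricity must be positive")

    # -- canned geometries --------------------------------------------------
    @classmethod
    def maculopapillary(cls, seed: int = 0, **overrides) -> "PhantomConfig":
        """Disc-to-periphery field: 12.8 x 0.96 mm at (50, 15, 3.1) µm.

        One grid spans the optic disc through ~7.5 mm temporal to the fovea,
        so peripapillary, parafoveal, perifoveal and peripheral sampling
        regions, and the ICP/DCP merge locus, all fit in a single volume.
        """
        return cls(seed=seed, **overrides)

    @classmethod
    def flat_macular(cls, seed: int = 0, **overrides) -> "PhantomConfig":
        """Flat layers (no pit, no NFL gain, disc outside grid), 15 µm pixels.

        The workhorse for calibration-style tests: 3.3 x 1.2 mm transverse.
        """
        defaults = dict(
            grid_shape=(220, 80, 176),
            voxel_spacing=(15.0, 15.0, 3.1),
            fovea_center=(0.45, 0.6),
            disc_center=(-10.0, 0.6),
            layer_params=LayerParams(pit_depth_um=0.0, nfl_peak_gain_um=0.0),
            merge_eccentricity=50.0,
            n_trees=0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    @classmethod
    def merge_study(cls, seed: int = 0, merge_eccentricity: float = 6.5, **overrides) -> "PhantomConfig":
        """Flat-layer strip for ICP/DCP merge localization: 9.0 x 0.96 mm.

        Fine 25 µm x-pitch, no large vessels and no disc in the grid, so
        depth profiles along the eccentricity axis isolate the two deep
        plexuses cleanly out to ~8 mm.
        """
        defaults = dict(
            grid_shape=(360, 64, 176),
            voxel_spacing=(25.0, 15.0, 3.1),
            fovea_center=(0.5, 0.48),
            disc_center=(-10.0, 0.48),
            layer_params=LayerParams(pit_depth_um=0.0, nfl_peak_gain_um=0.0),
            merge_eccentricity=merge_eccentricity,
            n_trees=0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def landmarks(self) -> Landmarks:
        return Landmarks(self.fovea_center, self.disc_center, self.disc_radius)


@dataclass
class PhantomTruth:
    """Ground truth emitted by the generator.

    ``in_situ_flow`` marks real generated flow; ``artifact_flow`` marks
    tail-only voxels (filled in by :func:`render_volume`); the two are
    disjoint.  ``plexus_depths`` holds the integer depth-plane map of each
    plexus centerline, and ``achieved_fractions`` the measured en-face
    capillary area fraction per plexus.
    """

    in_situ_flow: np.ndarray
    plexus_label: np.ndarray
    layer_model: LayerModel
    artifact_flow: np.ndarray | None = None
    enface_masks: dict[str, np.ndarray] = field(default_factory=dict)
    plexus_depths: dict[str, np.ndarray] = field(default_factory=dict)
    achieved_fractions: dict[str, float] = field(default_factory=dict)

    def label_name(self, code: int) -> str:
        return LABEL_NAMES[code]


# ---------------------------------------------------------------------------
# layer model
# ---------------------------------------------------------------------------

def generate_layer_model(config: PhantomConfig) -> LayerModel:
    """Build the seven ordered boundary surfaces z(x, y) in voxel units.

    All modulations are Gaussian in the transverse plane (band-limited).
    Inner layers thin toward zero at the fovea center; the NFL thickens
    toward the optic disc.  Raises :class:`LayerError` if the stack leaves
    the grid.
    """
    config.validate()
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.voxel_spacing
    lp = config.layer_params

    x = np.arange(nx)[:, None] * dx / 1000.0
    y = np.arange(ny)[None, :] * dy / 1000.0
    r_fov = np.hypot(x - config.fovea_center[0], y - config.fovea_center[1])
    r_disc = np.hypot(x - config.disc_center[0], y - config.disc_center[1])

    # foveal pit: remove pit_depth of inner-retina thickness, proportionally
    pit = np.exp(-0.5 * (r_fov / lp.pit_sigma_mm) ** 2)
    inner_total = lp.inner_total_um
    factor = 1.0 - (lp.pit_depth_um / inner_total) * pit if inner_total > 0 else 1.0
    factor = np.clip(factor, 0.05, None)

    nfl = lp.nfl_um * factor + lp.nfl_peak_gain_um * np.exp(
        -0.5 * (r_disc / lp.nfl_gain_sigma_mm) ** 2
    )
    gclipl = lp.gclipl_um * factor
    inl = lp.inl_um * factor
    opl = lp.opl_um * factor

    ilm = np.full((nx, ny), lp.vitreous_um)
    surfaces = {
        "ILM": ilm,
        "NFL/GCL": ilm + nfl,
        "IPL/INL": ilm + nfl + gclipl,
        "INL/OPL": ilm + nfl + gclipl + inl,
        "OPL/ONL": ilm + nfl + gclipl + inl + opl,
        "RPE": ilm + nfl + gclipl + inl + opl + lp.onl_um,
    }
    model = LayerModel({k: v / dz for k, v in surfaces.items()})
    model.validate(nz=nz)
    return model


# ---------------------------------------------------------------------------
# mesh synthesis helpers
# ---------------------------------------------------------------------------

def _voronoi_ridge_skeleton(shape, spacing_mm, lobule_mm, rng) -> np.ndarray:
    """Ridge pixels of a jittered-grid (blue-noise) Voronoi tessellation."""
    nx, ny = shape
    dx, dy = spacing_mm
    ext_x, ext_y = nx * dx, ny * dy
    ncx = max(2, int(np.ceil(ext_x / lobule_mm)) + 1)
    ncy = max(2, int(np.ceil(ext_y / lobule_mm)) + 1)
    cx = (np.arange(ncx) + 0.5) * lobule_mm - 0.5 * (ncx * lobule_mm - ext_x)
    cy = (np.arange(ncy) + 0.5) * lobule_mm - 0.5 * (ncy * lobule_mm - ext_y)
    seeds = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    seeds = seeds + rng.uniform(-0.45, 0.45, seeds.shape) * lobule_mm

    px = (np.arange(nx) + 0.5) * dx
    py = (np.arange(ny) + 0.5) * dy
    pts = np.stack(np.meshgrid(px, py, indexing="ij"), axis=-1).reshape(-1, 2)
    _, lab = cKDTree(seeds).query(pts)
    lab = lab.reshape(nx, ny)
    ridge = np.zeros((nx, ny), dtype=bool)
    ridge[:-1, :] |= lab[:-1, :] != lab[1:, :]
    ridge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    return ridge


def _dilate_to_fraction(
    skeleton: np.ndarray,
    region: np.ndarray,
    target: float,
    spacing_mm,
    max_radius_mm: float,
    rng,
) -> np.ndarray:
    """Dilate a skeleton so its area fraction inside ``region`` hits ``target``.

    Thresholds the (anisotropy-aware) distance transform at the exact target
    quantile of in-region distances; deterministic jitter breaks ties so the
    achieved count is exact to one pixel.
    """
    if not skeleton.any():
        raise AreaFractionError("empty skeleton: no capillary pattern to dilate")
    dist = distance_transform_edt(~skeleton, sampling=spacing_mm)
    jitter = rng.uniform(0.0, 1e-4 * min(spacing_mm), size=dist.shape)
    dist = dist + jitter
    vals = np.sort(dist[region])
    n = vals.size
    k = int(round(target * n))
    k = min(max(k, 1), n)
    r = vals[k - 1]
    if r > max_radius_mm:
        raise AreaFractionError(
            f"area fraction {target} needs dilation radius {r * 1000:.0f} µm "
            f"(limit {max_radius_mm * 1000:.0f} µm): unreachable at this capillary width"
        )
    return dist <= r


def _mesh_mask(
    shape, spacing_mm, params: PlexusParams, region, target, rng, extra_skeleton=None
) -> np.ndarray:
    """Lobular capillary mesh with calibrated area fraction inside ``region``.

    ``extra_skeleton`` (e.g. the perifoveal capillary ring) is merged into
    the skeleton before calibration so it is part of the area budget.
    """
    pitch = float(np.mean(spacing_mm))
    lobule = params.lobule_mm
    if lobule is None:
        # choose the mesh scale so the bare skeleton sits below the target
        lobule = max(2.0 * pitch / (0.55 * target), 3.0 * max(spacing_mm))
    width_mm = params.capillary_width_um / 1000.0
    max_r = max(2.0 * width_mm, 1.8 * max(spacing_mm))
    for _ in range(4):
        skel = _voronoi_ridge_skeleton(shape, spacing_mm, lobule, rng)
        if extra_skeleton is not None:
            skel = skel | extra_skeleton
        if skel[region].mean() <= 0.8 * target:
            break
        lobule *= 1.5
    else:
        raise AreaFractionError(
            f"skeleton fraction {skel[region].mean():.3f} exceeds target {target}"
        )
    return _dilate_to_fraction(skel, region, target, spacing_mm, max_r, rng)


def _radial_spoke_skeleton(
    config: PhantomConfig, rng, annulus: np.ndarray | None = None, target: float = 0.0
) -> np.ndarray:
    """Arcuate streamlines radiating from the optic disc edge (RPCP look).

    Spokes are added one at a time; if a calibration ``annulus`` and target
    fraction are given, accumulation stops as soon as the annulus coverage
    reaches the target, so the achieved fraction lands within one spoke's
    footprint of it.
    """
    nx, ny, _ = config.grid_shape
    dx, dy, _ = config.voxel_spacing
    sp = (dx / 1000.0, dy / 1000.0)
    cx, cy = config.disc_center
    r0 = config.disc_radius
    extent = config.rpcp_extent_mm
    params = config.plexus_params["RPCP"]
    width_mm = max(params.capillary_width_um / 1000.0, min(sp))
    # upper bound on the spoke count from the target fraction on the
    # annulus just outside the disc edge
    r_mid = r0 + 0.25
    n_max = max(8, 3 * int(round(params.area_fraction * 2 * np.pi * r_mid / width_mm)))
    n_annulus = int(annulus.sum()) if annulus is not None else 0
    mask = np.zeros((nx, ny), dtype=bool)
    step = 0.5 * min(sp)
    for _ in range(n_max):
        theta = rng.uniform(0, 2 * np.pi)
        length = extent * rng.uniform(0.35, 1.0)
        curvature = rng.uniform(-0.35, 0.35)  # rad per mm of radial travel
        rr = np.arange(r0, r0 + length, step)
        th = theta + curvature * (rr - r0)
        xs = np.round((cx + rr * np.cos(th)) / sp[0] - 0.5).astype(int)
        ys = np.round((cy + rr * np.sin(th)) / sp[1] - 0.5).astype(int)
        ok = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny)
        mask[xs[ok], ys[ok]] = True
        if n_annulus and mask[annulus].sum() >= target * n_annulus:
            break
    return mask


def _tree_mask(config: PhantomConfig, rng) -> np.ndarray:
    """Branching large-vessel trunks crossing the field in x."""
    nx, ny, _ = config.grid_shape
    dx, dy, _ = config.voxel_spacing
    mask = np.zeros((nx, ny), dtype=bool)
    if config.n_trees == 0:
        return mask
    half_w = 0.5 * config.tree_width_um / dy  # dilation below is in y pixels
    xs = np.arange(nx)
    for t in range(config.n_trees):
        y0 = ny * (t + 1) / (config.n_trees + 1)
        wander = np.cumsum(rng.normal(0, 0.35, nx))
        wander -= np.linspace(wander[0], wander[-1], nx)
        yc = y0 + wander + 2.0 * np.sin(2 * np.pi * xs / nx * rng.uniform(1, 2))
        ys = np.round(yc).astype(int)
        ok = (ys >= 0) & (ys < ny)
        mask[xs[ok], ys[ok]] = True
        # a few straight branches peeling off the trunk
        for _ in range(3):
            i0 = rng.integers(nx // 8, 7 * nx // 8)
            if not ok[i0]:
                continue
            slope = rng.choice([-1, 1]) * rng.uniform(0.2, 0.6)
            length = rng.integers(nx // 12, nx // 6)
            bx = np.arange(i0, min(nx, i0 + length))
            by = np.round(yc[i0] + slope * (bx - i0)).astype(int)
            bok = (by >= 0) & (by < ny)
            mask[bx[bok], by[bok]] = True
    # dilate to the vessel width (anisotropy-aware)
    dist = distance_transform_edt(~mask, sampling=(dx, dy))
    return dist <= 0.5 * config.tree_width_um


# ---------------------------------------------------------------------------
# vasculature
# ---------------------------------------------------------------------------

def _band_plane_index(z_float: np.ndarray, z_in: np.ndarray, z_out: np.ndarray) -> np.ndarray:
    """Round a centerline depth to a voxel plane, clamped inside [z_in, z_out).

    Integer planes inside a half-open band are ceil(z_in) .. ceil(z_out)-1.
    Columns with an empty band return -1.
    """
    lo = np.ceil(z_in - 1e-9).astype(int)
    hi = np.ceil(z_out - 1e-9).astype(int) - 1
    idx = np.clip(np.round(z_float).astype(int), lo, hi)
    idx[hi < lo] = -1
    return idx


def plexus_centerline_separation(config: PhantomConfig, eccentricity_mm) -> np.ndarray:
    """ICP/DCP centerline depth separation (voxels) at a given eccentricity.

    A linear ramp from the full INL thickness at the fovea down to zero at
    ``merge_eccentricity``.
    """
    e = np.asarray(eccentricity_mm, dtype=float)
    sep0 = config.layer_params.inl_um / config.voxel_spacing[2]
    return sep0 * np.clip(1.0 - e / config.merge_eccentricity, 0.0, None)


def generate_vasculature(config: PhantomConfig, layers: LayerModel) -> PhantomTruth:
    """Lay down the four plexuses, the FAZ ring, and interconnecting segments.

    Achieved capillary area fractions are calibrated against their targets
    inside each plexus' valid region (outside the FAZ and, for the SVP,
    outside the large-vessel trees).
    """
    config.validate()
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.voxel_spacing
    sp = (dx / 1000.0, dy / 1000.0)
    rng = np.random.default_rng(config.seed)

    x = (np.arange(nx)[:, None] + 0.5) * sp[0]
    y = (np.arange(ny)[None, :] + 0.5) * sp[1]
    r_fov = np.hypot(x - config.fovea_center[0], y - config.fovea_center[1])
    r_disc = np.hypot(x - config.disc_center[0], y - config.disc_center[1])

    faz = r_fov < config.faz_radius
    ring_w = max(config.plexus_params["SVP"].capillary_width_um / 1000.0, 1.2 * min(sp))
    faz_ring = (r_fov >= config.faz_radius) & (r_fov < config.faz_radius + ring_w)
    # the ring is locally dense extra anatomy: keep it out of the area-
    # fraction calibration so it does not dilute the mesh elsewhere
    ring_zone = r_fov < config.faz_radius + ring_w + 3.0 * max(sp)
    in_disc = r_disc < config.disc_radius

    trees = _tree_mask(config, rng) if "SVP" in config.plexus_params else np.zeros((nx, ny), bool)
    trees &= ~faz

    valid = ~faz & ~in_disc
    masks: dict[str, np.ndarray] = {}
    achieved: dict[str, float] = {}

    # --- capillary meshes -------------------------------------------------
    for name in ("SVP", "ICP", "DCP"):
        if name not in config.plexus_params:
            continue
        p = config.plexus_params[name]
        region = valid & ~ring_zone
        if name == "SVP":
            region &= ~trees
        if region.sum() < 100:
            raise AreaFractionError(f"no room to calibrate {name} capillary fraction")
        m = _mesh_mask((nx, ny), sp, p, region, p.area_fraction, rng, extra_skeleton=faz_ring)
        m &= ~faz
        masks[name] = m
        achieved[name] = float(m[region].mean())

    # --- radial peripapillary capillaries ---------------------------------
    if "RPCP" in config.plexus_params:
        p = config.plexus_params["RPCP"]
        nfl_thick = layers.thickness("ILM", "NFL/GCL")
        host = (nfl_thick >= 2.0) & ~in_disc & ~faz
        annulus = host & (r_disc >= config.disc_radius) & (r_disc < config.disc_radius + 0.5)
        if annulus.sum() >= 100:
            skel = _radial_spoke_skeleton(config, rng, annulus, p.area_fraction)
            if skel[annulus].mean() >= p.area_fraction:
                m = skel  # spoke accumulation already hit the target
            else:
                width_mm = p.capillary_width_um / 1000.0
                max_r = max(2.0 * width_mm, 1.8 * max(sp))
                m = _dilate_to_fraction(skel, annulus, p.area_fraction, sp, max_r, rng)
            m &= host
            masks["RPCP"] = m
            achieved["RPCP"] = float(m[annulus].mean())
        else:
            masks["RPCP"] = np.zeros((nx, ny), dtype=bool)  # disc out of grid

    # --- centerline depths -------------------------------------------------
    ilm = layers.surface("ILM")
    nflgcl = layers.surface("NFL/GCL")
    ipl_inl = layers.surface("IPL/INL")
    inl_opl = layers.surface("INL/OPL")
    opl_onl = layers.surface("OPL/ONL")
    gcc80 = ilm + 0.8 * (ipl_inl - ilm)
    inl_mid = 0.5 * (ipl_inl + inl_opl)

    ramp = np.clip(1.0 - r_fov / config.merge_eccentricity, 0.0, None)
    sep = (inl_opl - ipl_inl) * ramp
    # centerlines stay strictly inside the INL: at full separation they hug
    # the inner/outer INL borders, and coalesce at mid-INL when merged
    icp_z = np.clip(inl_mid - 0.5 * sep, ipl_inl + 0.51, inl_mid - 0.51)
    dcp_z = np.clip(inl_mid + 0.5 * sep, inl_mid, inl_opl - 0.51)

    depths = {
        "RPCP": _band_plane_index(0.5 * (ilm + nflgcl), ilm, nflgcl),
        "SVP": _band_plane_index(0.5 * (nflgcl + gcc80), nflgcl, gcc80),
        "ICP": _band_plane_index(icp_z, gcc80, inl_mid),
        "DCP": _band_plane_index(dcp_z, inl_mid, opl_onl),
    }

    # --- rasterize into the volume ----------------------------------------
    in_situ = np.zeros((nx, ny, nz), dtype=bool)
    label = np.zeros((nx, ny, nz), dtype=np.uint8)

    def _stamp(mask2d, zidx, code, axial_extra=0):
        ok = mask2d & (zidx >= 0)
        xs, ys = np.nonzero(ok)
        for off in range(-axial_extra, axial_extra + 1):
            zs = np.clip(zidx[xs, ys] + off, 0, nz - 1)
            fresh = ~in_situ[xs, ys, zs]
            in_situ[xs[fresh], ys[fresh], zs[fresh]] = True
            label[xs[fresh], ys[fresh], zs[fresh]] = code

    for name in ("RPCP", "SVP", "ICP", "DCP"):
        if name in masks:
            _stamp(masks[name], depths[name], PLEXUS_LABELS[name])
    if trees.any():
        _stamp(trees, depths["SVP"], PLEXUS_LABELS["SVP"], axial_extra=1)
        masks["SVP_trees"] = trees

    # --- vertical interconnects (SVP -> ICP / DCP) ------------------------
    if config.interconnect_fraction > 0 and "SVP" in masks and "DCP" in masks:
        cand = np.nonzero(masks["SVP"] & valid & (depths["SVP"] >= 0) & (depths["DCP"] >= 0))
        n_ic = int(round(config.interconnect_fraction * valid.sum()))
        if len(cand[0]) and n_ic:
            pick = rng.choice(len(cand[0]), size=min(n_ic, len(cand[0])), replace=False)
            code = PLEXUS_LABELS["interconnect"]
            for i in pick:
                cx_, cy_ = cand[0][i], cand[1][i]
                z_top = depths["SVP"][cx_, cy_]
                z_bot = depths["DCP" if rng.random() < 0.5 else "ICP"][cx_, cy_]
                for z in range(z_top + 1, z_bot):
                    if not in_situ[cx_, cy_, z]:
                        in_situ[cx_, cy_, z] = True
                        label[cx_, cy_, z] = code

    return PhantomTruth(
        in_situ_flow=in_situ,
        plexus_label=label,
        layer_model=layers,
        enface_masks=masks,
        plexus_depths=depths,
        achieved_fractions=achieved,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _reflectance_base(config: PhantomConfig, layers: LayerModel) -> np.ndarray:
    nx, ny, nz = config.grid_shape
    rp = config.reflectance_params
    z = np.arange(nz)[None, None, :]
    s = {k: layers.surface(k)[..., None] for k in BOUNDARIES}
    R = np.full((nx, ny, nz), rp.vitreous, dtype=np.float64)
    R = np.where((z >= s["ILM"]) & (z < s["NFL/GCL"]), rp.nfl, R)
    R = np.where((z >= s["NFL/GCL"]) & (z < s["IPL/INL"]), rp.gclipl, R)
    inl_thick = np.maximum(s["INL/OPL"] - s["IPL/INL"], 1e-6)
    frac = np.clip((z - s["IPL/INL"]) / inl_thick, 0, 1)
    inl_val = rp.inl_top + (rp.inl_bottom - rp.inl_top) * frac
    R = np.where((z >= s["IPL/INL"]) & (z < s["INL/OPL"]), inl_val, R)
    R = np.where((z >= s["INL/OPL"]) & (z < s["OPL/ONL"]), rp.opl, R)
    R = np.where((z >= s["OPL/ONL"]) & (z < s["RPE"]), rp.onl, R)
    rpe_band = rp.rpe_band_um / config.voxel_spacing[2]
    R = np.where((z >= s["RPE"]) & (z < s["RPE"] + rpe_band), rp.rpe, R)
    R = np.where(z >= s["RPE"] + rpe_band, rp.below, R)
    return R


def _inner_retina_median(R: np.ndarray, layers: LayerModel) -> float:
    """Median reflectance over the inner retina [ILM, OPL/ONL)."""
    nz = R.shape[2]
    z = np.arange(nz)
    band = (z >= layers.surface("ILM")[..., None]) & (z < layers.surface("OPL/ONL")[..., None])
    return float(np.median(R[band]))


def render_volume(
    config: PhantomConfig,
    truth: PhantomTruth,
    monotone_in_situ: bool = False,
) -> OctaVolume:
    """Render reflectance + decorrelation grids and fill projection tails.

    In-situ flow voxels draw decorrelation from U[0.3, 0.6] (above the 0.12
    large-vessel threshold scale, inside the bounded SSADA range).  With
    ``monotone_in_situ`` the in-situ values are instead assigned so that
    reflectance-normalized decorrelation strictly increases with depth in
    every A-scan — the constructed best case in which projection resolution
    should retain every real flow voxel.

    Artifact-only voxels (tail, no in-situ flow) are recorded in
    ``truth.artifact_flow``.
    """
    if truth.in_situ_flow.shape != tuple(config.grid_shape):
        raise ValueError("truth grids do not match the config grid shape")
    nx, ny, nz = config.grid_shape
    dz_mm = config.voxel_spacing[2] / 1000.0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    noise = config.noise_params

    R_base = _reflectance_base(config, truth.layer_model)
    if noise.speckle_contrast > 0:
        R = R_base * np.clip(rng.normal(1.0, noise.speckle_contrast, R_base.shape), 0.05, None)
    else:
        R = R_base.copy()

    D = np.zeros((nx, ny, nz), dtype=np.float64)
    in_situ = truth.in_situ_flow
    if monotone_in_situ:
        r_ref = _inner_retina_median(R, truth.layer_model)
        norm = np.maximum(R / r_ref, 0.1)
        for cx, cy in zip(*np.nonzero(in_situ.any(axis=2))):
            zs = np.nonzero(in_situ[cx, cy, :])[0]
            targets = np.linspace(0.35, 0.9, len(zs))
            vals = np.minimum(targets * norm[cx, cy, zs], 0.999)
            D[cx, cy, zs] = vals
    else:
        vessel3d = np.zeros_like(in_situ)
        trees2d = truth.enface_masks.get("SVP_trees")
        if trees2d is not None:
            vessel3d = trees2d[..., None] & in_situ & (
                truth.plexus_label == PLEXUS_LABELS["SVP"]
            )
        cap = in_situ & ~vessel3d
        D[cap] = rng.uniform(*config.capillary_flow_range, size=int(cap.sum()))
        D[vessel3d] = rng.uniform(*config.vessel_flow_range, size=int(vessel3d.sum()))

    # Projection tails: reflectance-gated exponential decay under each source.
    # Tail strength follows the *mean* tissue reflectance (the shadow's
    # visibility on a layer), not the per-voxel speckle draw — decorrelation
    # is a normalized statistic, so speckle amplitude largely divides out.
    alpha = config.tail_params.alpha_per_mm
    gate = config.tail_params.reflectance_gate
    contrast = config.tail_params.tail_contrast
    artifact = np.zeros_like(D)
    xs, ys, zs = np.nonzero(in_situ) if alpha > 0 else (np.array([], int),) * 3
    order = np.lexsort((zs, ys, xs))
    for i in order:
        x0, y0, z0 = xs[i], ys[i], zs[i]
        if z0 + 1 >= nz:
            continue
        r_col = R_base[x0, y0, z0 + 1:]
        d_src, r_src = D[x0, y0, z0], max(R_base[x0, y0, z0], 1e-9)
        decay = alpha ** (np.arange(1, nz - z0) * dz_mm)
        contrib = contrast * d_src * decay * np.minimum(r_col / r_src, 1.0)
        contrib[r_col < gate] = 0.0
        np.maximum(artifact[x0, y0, z0 + 1:], contrib, out=artifact[x0, y0, z0 + 1:])

    truth.artifact_flow = (artifact > 1e-9) & ~in_situ
    D = np.where(in_situ, D, artifact)
    if noise.decorrelation_noise > 0:
        D = D + np.abs(rng.normal(0.0, noise.decorrelation_noise, D.shape))
    D = np.clip(D, 0.0, 1.0)

    return OctaVolume(
        reflectance=R.astype(np.float32),
        decorrelation=D.astype(np.float32),
        voxel_spacing=config.voxel_spacing,
        landmarks=config.landmarks(),
    )


def generate_phantom(
    config: PhantomConfig, monotone_in_situ: bool = False
) -> tuple[OctaVolume, PhantomTruth]:
    """Layer model -> vasculature -> rendered volume, in one call."""
    layers = generate_layer_model(config)
    truth = generate_vasculature(config, layers)
    volume = render_volume(config, truth, monotone_in_situ=monotone_in_situ)
    return volume, truth


def noise_free(config: PhantomConfig) -> PhantomConfig:
    """Copy of a config with speckle and decorrelation noise switched off."""
    return replace(config, noise_params=NoiseParams(0.0, 0.0))
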