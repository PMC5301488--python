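"""Core containers shared by every pipeline stage.

Conventions
-----------
Grids are indexed ``[x, y, z]`` with shape ``(nx, ny, nz)``.  The depth index
``z`` runs from the vitreous side downward: ``z = 0`` is the innermost plane
and "shallower" always means smaller ``z``.  Transverse positions are given in
millimetres from the grid origin (``x_mm = i * dx / 1000``); the positive x
direction points temporally, so the optic disc sits at smaller x than the
fovea and eccentricity temporal to the fovea grows with x.

Decorrelation is the SSADA-scale flow signal in [0, 1]; reflectance is a
nonnegative structural signal in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Anatomic boundary surfaces, ordered from the vitreous downward.
BOUNDARIES: tuple[str, ...] = ("ILM", "NFL/GCL", "IPL/INL", "INL/OPL", "OPL/ONL", "RPE")


@dataclass(frozen=True)
class Landmarks:
    """Transverse landmark positions in grid millimetres."""

    fovea: tuple[float, float]
    disc_center: tuple[float, float]
    disc_radius: float = 0.75

    @property
    def disc_edge_x(self) -> float:
        """x position of the temporal disc edge (mm, grid coordinates)."""
        return self.disc_center[0] + self.disc_radius

    def eccentricity_from_fovea(self, x_mm, y_mm):
        """Euclidean transverse distance (mm) from the foveal center."""
        return np.hypot(np.asarray(x_mm) - self.fovea[0], np.asarray(y_mm) - self.fovea[1])


class LayerError(ValueError):
    """A layer model violates ordering or range constraints."""


@dataclass
class LayerModel:
    """Per-(x, y) depth surfaces for the retinal anatomic boundaries.

    Surfaces are z positions in (fractional) voxel units, one 2-D map per
    boundary name in :data:`BOUNDARIES`.  At every column the surfaces must be
    ordered ILM <= NFL/GCL <= IPL/INL <= INL/OPL <= OPL/ONL <= RPE.
    """

    surfaces: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [b for b in BOUNDARIES if b not in self.surfaces]
        if missing:
            raise LayerError(f"missing boundary surfaces: {missing}")
        shape = self.shape
        for name, surf in self.surfaces.items():
            if surf.shape != shape:
                raise LayerError(f"surface {name!r} has shape {surf.shape}, expected {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.surfaces[BOUNDARIES[0]].shape

    def surface(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def validate(self, nz: int | None = None) -> None:
        """Check boundary ordering (and optionally the [0, nz) range)."""
        for upper, lower in zip(BOUNDARIES[:-1], BOUNDARIES[1:]):
            diff = self.surfaces[lower] - self.surfaces[upper]
            if np.any(diff < -1e-9):
                idx = np.unravel_index(np.argmin(diff), diff.shape)
                raise LayerError(
                    f"boundary order violated: {lower} above {upper} at (x,y)={idx}"
                )
        if nz is not None:
            for name, surf in self.surfaces.items():
                if surf.min() < 0 or surf.max() >= nz:
                    raise LayerError(f"surface {name!r} leaves the grid [0, {nz})")

    def thickness(self, upper: str, lower: str) -> np.ndarray:
        """Thickness map (voxels) of the band between two boundaries."""
        return self.surfaces[lower] - self.surfaces[upper]

    def shifted(self, dz) -> "LayerModel":
        """New model with every surface shifted by ``dz`` (scalar or map)."""
        return LayerModel({k: v + dz for k, v in self.surfaces.items()})

    def copy(self) -> "LayerModel":
        return LayerModel({k: v.copy() for k, v in self.surfaces.items()})


@dataclass
class OctaVolume:
    """Co-registered reflectance + decorrelation volume.

    Parameters
    ----------
    reflectance, decorrelation : float arrays, shape (nx, ny, nz)
    voxel_spacing : (dx, dy, dz) in micrometres
    landmarks : fovea / optic-disc positions in grid mm
    """

    reflectance: np.ndarray
    decorrelation: np.ndarray
    voxel_spacing: tuple[float, float, float]
    landmarks: Landmarks | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float32)
        self.decorrelation = np.asarray(self.decorrelation, dtype=np.float32)
        self.validate()

    def validate(self) -> None:
        if self.reflectance.shape != self.decorrelation.shape:
            raise ValueError(
                f"grid shape mismatch: reflectance {self.reflectance.shape} "
                f"vs decorrelation {self.decorrelation.shape}"
            )
        if self.reflectance.ndim != 3:
            raise ValueError("volumes must be 3-D (nx, ny, nz)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if np.any(self.reflectance < 0):
            raise ValueError("reflectance must be nonnegative")
        dmin, dmax = float(self.decorrelation.min()), float(self.decorrelation.max())
        if dmin < 0 or dmax > 1:
            raise ValueError(f"decorrelation outside [0, 1]: range [{dmin}, {dmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    # -- coordinate helpers -------------------------------------------------
    def x_mm(self) -> np.ndarray:
        return np.arange(self.shape[0]) * self.voxel_spacing[0] / 1000.0

    def y_mm(self) -> np.ndarray:
        return np.arange(self.shape[1]) * self.voxel_spacing[1] / 1000.0

    def mm_to_index(self, x_mm: float, y_mm: float) -> tuple[int, int]:
        dx, dy, _ = self.voxel_spacing
        return int(round(x_mm * 1000.0 / dx)), int(round(y_mm * 1000.0 / dy))

    def copy(self) -> "OctaVolume":
        return OctaVolume(
            self.reflectance.copy(),
            self.decorrelation.copy(),
            self.voxel_spacing,
            self.landmarks,
        )


@dataclass
class NormalizedVolume:
    """A volume resampled onto a reference anatomy.

    ``layers`` are the boundary surfaces valid for the *resampled* grid (the
    reference model after flattening/depth scaling).  ``invalid_columns``
    flags (x, y) columns whose resampling was degenerate (e.g. a
    zero-thickness source layer where the reference is nonzero); density
    profiling excludes them.
    """

    volume: OctaVolume
    layers: LayerModel
    reference: str = "self"
    invalid_columns: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        nx, ny, _ = self.volume.shape
        if self.layers.shape != (nx, ny):
            raise ValueError("layer model shape does not match volume transverse shape")
        if self.invalid_columns is None:
            self.invalid_columns = np.zeros((nx, ny), dtype=bool)
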