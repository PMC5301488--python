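"""En-face projections and composite cross-sections.

Angiograms are maximum flow projections over a slab; structural images are
reflectance means over the slab.  Maximum projection uses the voxels whose
centers fall inside the half-open band (threshold-sensitive, so no partial
voxels); the mean uses partial-voxel weights at the fractional band edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LayerModel, OctaVolume


@dataclass
class EnfaceImage:
    """2-D projection of a depth band.

    ``absent`` flags columns whose band contained no (partial) voxel.
    """

    data: np.ndarray
    modality: str  # "flow-max" | "reflectance-mean"
    slab: str
    spacing_mm: tuple[float, float]
    absent: np.ndarray | None = None


def project_flow_max(
    volume: OctaVolume, band: tuple[np.ndarray, np.ndarray], slab: str = ""
) -> EnfaceImage:
    """Per-column maximum decorrelation over voxels with centers in the band."""
    z_in, z_out = band
    nz = volume.shape[2]
    z = np.arange(nz)
    member = (z >= z_in[..., None]) & (z < z_out[..., None])
    d = np.where(member, volume.decorrelation, -np.inf).max(axis=2)
    absent = ~member.any(axis=2)
    d = np.where(absent, 0.0, d)
    dx, dy, _ = volume.voxel_spacing
    return EnfaceImage(d.astype(np.float32), "flow-max", slab, (dx / 1000.0, dy / 1000.0), absent)


def project_reflectance_mean(
    volume: OctaVolume, band: tuple[np.ndarray, np.ndarray], slab: str = ""
) -> EnfaceImage:
    """Reflectance average over the band with partial-voxel edge weights.

    Voxel k covers [k - 0.5, k + 0.5); its weight is the overlap length with
    [z_in, z_out), so two adjacent half-bands average exactly to the full
    band's value.
    """
    z_in, z_out = band
    nz = volume.shape[2]
    z = np.arange(nz)
    lo = np.maximum(z - 0.5, z_in[..., None])
    hi = np.minimum(z + 0.5, z_out[..., None])
    w = np.clip(hi - lo, 0.0, 1.0)
    total = w.sum(axis=2)
    absent = total <= 1e-12
    mean = (w * volume.reflectance).sum(axis=2) / np.where(absent, 1.0, total)
    mean = np.where(absent, 0.0, mean)
    dx, dy, _ = volume.voxel_spacing
    return EnfaceImage(
        mean.astype(np.float32), "reflectance-mean", slab, (dx / 1000.0, dy / 1000.0), absent
    )


#: display colors for the composite overlay (RGB in [0, 1])
RETINA_COLOR = (0.55, 0.2, 0.8)  # purple
CHOROID_COLOR = (0.9, 0.15, 0.1)  # red


def composite_cross_section(
    volume: OctaVolume,
    y_index: int,
    layers: LayerModel,
    flow_threshold: float = 0.0,
    display_max: float = 0.6,
) -> np.ndarray:
    """Grayscale reflectance B-scan with flow overlaid by compartment.

    Suprathreshold flow voxels above the RPE surface are painted the retinal
    color, those below the choroidal color.  Returns an (nx, nz, 3) RGB
    array in [0, 1]; reflectance is scaled to its 99th percentile and flow
    display-scaled linearly over [0, ``display_max``] (display only — never
    used in any quantitative path).
    """
    if not 0 <= y_index < volume.shape[1]:
        raise IndexError(f"y_index {y_index} outside grid")
    refl = volume.reflectance[:, y_index, :].astype(np.float64)
    flow = volume.decorrelation[:, y_index, :].astype(np.float64)
    scale = max(np.percentile(refl, 99), 1e-9)
    gray = np.clip(refl / scale, 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    rpe = layers.surface("RPE")[:, y_index]
    z = np.arange(volume.shape[2])[None, :]
    is_flow = flow > flow_threshold
    strength = np.clip(flow / display_max, 0.0, 1.0)
    for region, color in ((z < rpe[:, None], RETINA_COLOR), (z >= rpe[:, None], CHOROID_COLOR)):
        sel = is_flow & region
        for c in range(3):
            rgb[..., c][sel] = (1 - strength[sel]) * gray[sel] + strength[sel] * color[c]
    return rgb
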