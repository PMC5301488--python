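"""Fractional slab definitions for the retinal vascular plexuses.

A slab is a depth band bounded by two surfaces, each defined as a fractional
position between two named anatomic boundaries: ``surface = A + f * (B - A)``.
The plexus set used throughout:

* RPCP  — ILM to the NFL/GCL interface (radial peripapillary capillaries),
* SVP   — NFL/GCL interface to the inner 80% of the ganglion cell complex
  (GCC = NFL + GCL + IPL, i.e. ILM to IPL/INL),
* ICP   — outer 20% of the GCC to the inner 50% of the INL,
* DCP   — outer 50% of the INL to the outer boundary of the OPL,

with the complexes SVC = RPCP + SVP and DVC = ICP + DCP.  Bands are half-open
``[z_in, z_out)`` in voxel index so the four plexus bands partition the inner
retina ``[ILM, OPL/ONL)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BOUNDARIES, LayerModel


@dataclass(frozen=True)
class BoundaryOffset:
    """A surface at fractional position ``frac`` between boundaries A and B."""

    start: str
    end: str
    frac: float = 0.0

    def resolve(self, layers: LayerModel) -> np.ndarray:
        a = layers.surface(self.start)
        if self.frac == 0.0:
            return a.copy()
        b = layers.surface(self.end)
        return a + self.frac * (b - a)


@dataclass(frozen=True)
class SlabSpec:
    """A named depth band between two fractional boundary offsets."""

    name: str
    inner: BoundaryOffset
    outer: BoundaryOffset


class SlabError(ValueError):
    pass


def resolve_slab(spec: SlabSpec, layers: LayerModel) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a slab spec to per-column depth maps ``(z_in, z_out)``.

    The band is half-open ``[z_in, z_out)``; an inverted band anywhere raises
    :class:`SlabError` naming the offending column.
    """
    for off in (spec.inner, spec.outer):
        for b in (off.start, off.end):
            if b not in BOUNDARIES:
                raise SlabError(f"slab {spec.name!r} references unknown boundary {b!r}")
    z_in = spec.inner.resolve(layers)
    z_out = spec.outer.resolve(layers)
    bad = z_out - z_in < -1e-9
    if np.any(bad):
        idx = np.unravel_index(np.argmax(bad), bad.shape)
        raise SlabError(f"slab {spec.name!r} inverted at (x,y)={idx}")
    return z_in, z_out


# Inner 80% limit of the ganglion cell complex (ILM -> IPL/INL).
_GCC80 = BoundaryOffset("ILM", "IPL/INL", 0.8)
# Inner 50% limit of the inner nuclear layer.
_INL50 = BoundaryOffset("IPL/INL", "INL/OPL", 0.5)


def standard_plexus_specs() -> dict[str, SlabSpec]:
    """The standard plexus / complex slab set.

    RPCP, SVP, ICP, DCP tile the inner retina ``[ILM, OPL/ONL)``;
    SVC = RPCP + SVP, DVC = ICP + DCP, and ``retina`` is the full inner band.
    """
    ilm = BoundaryOffset("ILM", "ILM")
    nflgcl = BoundaryOffset("NFL/GCL", "NFL/GCL")
    opl_outer = BoundaryOffset("OPL/ONL", "OPL/ONL")
    return {
        "RPCP": SlabSpec("RPCP", ilm, nflgcl),
        "SVP": SlabSpec("SVP", nflgcl, _GCC80),
        "ICP": SlabSpec("ICP", _GCC80, _INL50),
        "DCP": SlabSpec("DCP", _INL50, opl_outer),
        "SVC": SlabSpec("SVC", ilm, _GCC80),
        "DVC": SlabSpec("DVC", _GCC80, opl_outer),
        "retina": SlabSpec("retina", ilm, opl_outer),
    }


def interplexus_slabs(layers: LayerModel) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Single-voxel-thick bands through the two inter-plexus spaces.

    The SVP/ICP space lies in the IPL: the band is centered at the midpoint
    between the inner-80%-GCC limit and the IPL/INL interface.  The ICP/DCP
    space lies in the INL: the band is centered at the INL midpoint.  Each
    band is exactly one voxel thick, ``[c - 0.5, c + 0.5)``.
    """
    gcc80 = _GCC80.resolve(layers)
    ipl_inl = layers.surface("IPL/INL")
    inl_opl = layers.surface("INL/OPL")
    ipl_center = 0.5 * (gcc80 + ipl_inl)
    inl_center = 0.5 * (ipl_inl + inl_opl)
    return {
        "IPL": (ipl_center - 0.5, ipl_center + 0.5),
        "INL": (inl_center - 0.5, inl_center + 0.5),
    }


def band_indices(z_in: np.ndarray, z_out: np.ndarray, nz: int) -> np.ndarray:
    """Boolean (nx, ny, nz) membership of voxel *centers* in ``[z_in, z_out)``."""
    z = np.arange(nz)
    return (z >= z_in[..., None]) & (z < z_out[..., None])
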