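"""Inter-subject normalization: RPE flattening, per-layer depth scaling,
and transverse disc–fovea registration.

Depth scaling resamples each major structural layer group (ILM+NFL,
GCL+IPL, INL, OPL, and the outer retina to the RPE) so its thickness
matches a reference subject; the segments above the ILM and below the RPE
are shifted rigidly.  Decorrelation is resampled with nearest-neighbor
lookup — interpolating flow would smear values across the noise threshold —
while reflectance is interpolated linearly.  The transverse axis is scaled
by the affine map sending the subject's disc and fovea centers onto the
reference's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BOUNDARIES, Landmarks, LayerModel, NormalizedVolume, OctaVolume


@dataclass
class FlattenResult:
    volume: OctaVolume
    layers: LayerModel
    clipped_columns: np.ndarray  # columns whose content left the grid


def flatten_shifts(layers: LayerModel) -> tuple[np.ndarray, int]:
    """Per-column integer shifts aligning the RPE at its deepest position."""
    rpe = np.round(layers.surface("RPE")).astype(int)
    z_target = int(rpe.max())
    return z_target - rpe, z_target


def flatten_to_rpe(volume: OctaVolume, layers: LayerModel) -> FlattenResult:
    """Shift each A-scan by an integer offset so the RPE sits at one depth.

    The target depth is the deepest rounded RPE position, so shifts are
    nonnegative (content moves deeper, zero-padded from the vitreous side);
    columns whose deep content is pushed past the grid are flagged.
    Idempotent: a flat RPE produces the identity.
    """
    nx, ny, nz = volume.shape
    shift, z_target = flatten_shifts(layers)  # >= 0
    z = np.arange(nz)
    src = z[None, None, :] - shift[..., None]
    valid = src >= 0
    src_c = np.clip(src, 0, nz - 1)
    take = np.take_along_axis  # noqa: E731 - alias for readability
    refl = np.where(valid, take(volume.reflectance, src_c, axis=2), 0.0)
    deco = np.where(valid, take(volume.decorrelation, src_c, axis=2), 0.0)
    out = OctaVolume(refl, deco, volume.voxel_spacing, volume.landmarks)
    clipped = (layers.surface("RPE") + shift) > (nz - 1)
    return FlattenResult(out, layers.shifted(shift.astype(float)), clipped)


def _control_points(layers: LayerModel, col: tuple[int, int]) -> np.ndarray:
    return np.array([layers.surface(b)[col] for b in BOUNDARIES])


def normalize_depth(
    volume: OctaVolume,
    layers: LayerModel,
    reference_layers: LayerModel,
    min_thickness: float = 0.5,
) -> NormalizedVolume:
    """Resample depth so every layer matches the reference thickness.

    Builds a per-column monotone piecewise-linear map from reference depth
    to source depth with control points at the anatomic boundaries, extended
    by rigid shifts above the ILM and below the RPE.  Reflectance is
    interpolated linearly; flow takes the *maximum* of the source voxels
    spanned by each output voxel (nearest source voxel where the span is
    empty), so thin flow sheets are neither smeared across the noise
    threshold nor dropped when a layer is compressed.  Columns where a
    source layer is (near) zero-thickness while the reference is not are
    flagged invalid and excluded from downstream profiling.
    """
    nx, ny, nz = volume.shape
    if layers.shape != (nx, ny) or reference_layers.shape != (nx, ny):
        raise ValueError("layer models must match the volume transverse shape")
    refl_out = np.zeros_like(volume.reflectance, dtype=np.float64)
    deco_out = np.zeros_like(volume.decorrelation, dtype=np.float64)
    invalid = np.zeros((nx, ny), dtype=bool)
    z_grid = np.arange(nz, dtype=float)
    z_edges = np.arange(nz + 1, dtype=float) - 0.5
    R = volume.reflectance.astype(np.float64)
    D = volume.decorrelation.astype(np.float64)
    for ix in range(nx):
        for iy in range(ny):
            src = _control_points(layers, (ix, iy))
            ref = _control_points(reference_layers, (ix, iy))
            src_th = np.diff(src)
            ref_th = np.diff(ref)
            if np.any((src_th < min_thickness) & (ref_th >= 2 * min_thickness)):
                invalid[ix, iy] = True
            # rigid extension above ILM and below RPE
            ref_cp = np.concatenate(([0.0], ref, [nz - 1.0 + ref[-1] + 1]))
            src_cp = np.concatenate(
                ([src[0] - ref[0]], src, [src[-1] + (nz - 1.0 + ref[-1] + 1 - ref[-1])])
            )
            # enforce strictly increasing abscissae for interpolation
            ref_cp = np.maximum.accumulate(ref_cp + 1e-9 * np.arange(ref_cp.size))
            src_cp = np.maximum.accumulate(src_cp)
            src_pos = np.interp(z_grid, ref_cp, src_cp)
            refl_out[ix, iy] = np.interp(src_pos, z_grid, R[ix, iy])

            # flow: max over source voxels whose centers fall in the span
            src_edge = np.interp(z_edges, ref_cp, src_cp)
            k0 = np.clip(np.ceil(src_edge[:-1] - 1e-9).astype(int), 0, nz)
            k1 = np.clip(np.ceil(src_edge[1:] - 1e-9).astype(int), 0, nz)
            col = D[ix, iy]
            nn = np.clip(np.round(src_pos).astype(int), 0, nz - 1)
            out_col = col[nn]  # empty spans: nearest source voxel
            one = (k1 - k0) == 1
            out_col[one] = col[k0[one]]
            for z in np.nonzero(k1 - k0 > 1)[0]:  # compressed spans only
                out_col[z] = col[k0[z]:k1[z]].max()
            oob = (src_pos < -0.5) | (src_pos > nz - 0.5)
            deco_out[ix, iy] = np.where(oob, 0.0, out_col)
    out = OctaVolume(refl_out, deco_out, volume.voxel_spacing, volume.landmarks)
    return NormalizedVolume(
        volume=out,
        layers=reference_layers.copy(),
        reference="depth-normalized",
        invalid_columns=invalid,
    )


def normalize_transverse(
    nvol: NormalizedVolume,
    landmarks: Landmarks,
    reference_landmarks: Landmarks,
) -> NormalizedVolume:
    """Affine x-rescale sending (disc, fovea) onto the reference positions."""
    volume = nvol.volume
    nx, ny, nz = volume.shape
    dx_mm = volume.voxel_spacing[0] / 1000.0
    f_ref, d_ref = reference_landmarks.fovea[0], reference_landmarks.disc_center[0]
    f_src, d_src = landmarks.fovea[0], landmarks.disc_center[0]
    if abs(d_ref - f_ref) < 1e-9:
        raise ValueError("reference disc and fovea coincide in x")
    a = (d_src - f_src) / (d_ref - f_ref)
    x_out = (np.arange(nx) + 0.5) * dx_mm
    x_src_mm = f_src + a * (x_out - f_ref)
    pos = x_src_mm / dx_mm - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, nx - 1)
    i1 = np.clip(i0 + 1, 0, nx - 1)
    t = np.clip(pos - i0, 0.0, 1.0)
    oob = (pos < -0.5) | (pos > nx - 0.5)
    refl = (1 - t)[:, None, None] * volume.reflectance[i0] + t[:, None, None] * volume.reflectance[i1]
    nn = np.clip(np.round(pos).astype(int), 0, nx - 1)
    deco = volume.decorrelation[nn]
    refl[oob] = 0.0
    deco[oob] = 0.0
    surfaces = {k: v[nn] for k, v in nvol.layers.surfaces.items()}
    invalid = nvol.invalid_columns[nn] | oob[:, None]
    out = OctaVolume(refl, deco, volume.voxel_spacing, reference_landmarks)
    return NormalizedVolume(
        volume=out,
        layers=LayerModel(surfaces),
        reference=nvol.reference + "+transverse",
        invalid_columns=invalid,
    )


def normalize_volume(
    volume: OctaVolume,
    layers: LayerModel,
    reference_layers: LayerModel | None = None,
    reference_landmarks: Landmarks | None = None,
) -> NormalizedVolume:
    """Flatten to the RPE and depth-normalize (to self if no reference).

    The reference layer model is flattened with the same rule before use, so
    passing the volume's own layers yields an (interpolation-exact) identity.
    """
    flat = flatten_to_rpe(volume, layers)
    if reference_layers is None:
        ref_flat_layers = flat.layers
    else:
        rpe = np.round(reference_layers.surface("RPE")).astype(int)
        ref_flat_layers = reference_layers.shifted((rpe.max() - rpe).astype(float))
    nvol = normalize_depth(flat.volume, flat.layers, ref_flat_layers)
    nvol.invalid_columns |= flat.clipped_columns
    if reference_landmarks is not None and volume.landmarks is not None:
        nvol = normalize_transverse(nvol, volume.landmarks, reference_landmarks)
    return nvol
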