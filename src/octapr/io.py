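"""Container I/O: HDF5 volumes, TIFF images, CSV tables.

One HDF5 file per volume holds the reflectance and decorrelation grids,
voxel spacing, landmarks, optional ground-truth grids and layer surfaces,
and a provenance block (config hash, seed, package version).  Writers are
deterministic byte-for-byte for identical inputs; round-trips reproduce
grids bit-exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import h5py
import tifffile

from .core import BOUNDARIES, Landmarks, LayerModel, OctaVolume
from .phantom import PhantomTruth

FORMAT_VERSION = 1


class ContainerFormatError(IOError):
    """The file is not a valid octapr volume container."""


def _write_layers(group: h5py.Group, layers: LayerModel) -> None:
    for name in BOUNDARIES:
        ds = group.create_dataset(name.replace("/", "__"), data=layers.surface(name), track_times=False)
        ds.attrs["boundary"] = name


def _read_layers(group: h5py.Group) -> LayerModel:
    surfaces = {}
    for key in group:
        surfaces[str(group[key].attrs["boundary"])] = group[key][()]
    return LayerModel(surfaces)


def write_container(
    path,
    volume: OctaVolume,
    truth: PhantomTruth | None = None,
    provenance: dict | None = None,
    overwrite: bool = False,
) -> None:
    """Persist a volume (and optional phantom truth) to one HDF5 file."""
    mode = "w" if overwrite else "w-"
    try:
        f = h5py.File(path, mode, track_order=True)
    except (OSError, FileExistsError) as exc:
        raise FileExistsError(f"refusing to overwrite {path} (pass overwrite=True)") from exc
    with f:
        f.attrs["format"] = "octapr-volume"
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["voxel_spacing_um"] = np.asarray(volume.voxel_spacing, dtype=float)
        if volume.landmarks is not None:
            lm = volume.landmarks
            f.attrs["fovea_mm"] = np.asarray(lm.fovea, dtype=float)
            f.attrs["disc_center_mm"] = np.asarray(lm.disc_center, dtype=float)
            f.attrs["disc_radius_mm"] = float(lm.disc_radius)
        for key, val in (provenance or {}).items():
            f.attrs[f"provenance_{key}"] = val
        f.create_dataset("reflectance", data=volume.reflectance, track_times=False)
        f.create_dataset("decorrelation", data=volume.decorrelation, track_times=False)
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("in_situ_flow", data=truth.in_situ_flow, track_times=False)
            g.create_dataset("plexus_label", data=truth.plexus_label, track_times=False)
            if truth.artifact_flow is not None:
                g.create_dataset("artifact_flow", data=truth.artifact_flow, track_times=False)
            _write_layers(g.create_group("layers"), truth.layer_model)
            gd = g.create_group("depths")
            for name, grid in truth.plexus_depths.items():
                gd.create_dataset(name, data=grid, track_times=False)
            for name, frac in truth.achieved_fractions.items():
                g.attrs[f"achieved_fraction_{name}"] = frac


def read_container(path) -> tuple[OctaVolume, PhantomTruth | None]:
    """Read a container back; raises :class:`ContainerFormatError` on junk."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerFormatError(f"{path} is not a readable HDF5 container") from exc
    with f:
        if f.attrs.get("format") != "octapr-volume":
            raise ContainerFormatError(f"{path} lacks the octapr-volume signature")
        spacing = tuple(float(s) for s in f.attrs["voxel_spacing_um"])
        landmarks = None
        if "fovea_mm" in f.attrs:
            landmarks = Landmarks(
                fovea=tuple(f.attrs["fovea_mm"]),
                disc_center=tuple(f.attrs["disc_center_mm"]),
                disc_radius=float(f.attrs["disc_radius_mm"]),
            )
        volume = OctaVolume(
            reflectance=f["reflectance"][()],
            decorrelation=f["decorrelation"][()],
            voxel_spacing=spacing,
            landmarks=landmarks,
        )
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = PhantomTruth(
                in_situ_flow=g["in_situ_flow"][()].astype(bool),
                plexus_label=g["plexus_label"][()],
                layer_model=_read_layers(g["layers"]),
                artifact_flow=(
                    g["artifact_flow"][()].astype(bool) if "artifact_flow" in g else None
                ),
                plexus_depths={k: g["depths"][k][()] for k in g.get("depths", {})},
                achieved_fractions={
                    k.removeprefix("achieved_fraction_"): float(v)
                    for k, v in g.attrs.items()
                    if k.startswith("achieved_fraction_")
                },
            )
    return volume, truth


def export_tables(obj, path) -> None:
    """Write a profile/map/findings object (or DataFrame) as headered CSV.

    Floats carry 10 significant digits, so a reread equals the written
    values to well beyond 9 significant digits.  Output bytes are a pure
    function of the data.
    """
    df = obj if isinstance(obj, pd.DataFrame) else obj.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_enface_tiff(path, images: dict[str, np.ndarray]) -> None:
    """Multi-page float32 TIFF, one page per named en-face image."""
    pages = [np.asarray(img, dtype=np.float32).T for img in images.values()]
    tifffile.imwrite(
        path, np.stack(pages), photometric="minisblack",
        metadata={"slabs": list(images)},
    )
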