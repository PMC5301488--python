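"""Peak/trough detection in depth-density profiles and plexus labeling.

A depth profile through the macula shows three density peaks (SVP in the
GCL, ICP at the inner INL border, DCP at the outer INL border) separated by
two troughs; peripapillary profiles add an NFL peak (RPCP) without a
distinct trough before the SVP; peripherally the ICP and DCP coalesce into
a single peak.  Peaks are labeled purely by the anatomic band containing
their depth, and the eccentricity at which the deep vascular complex first
holds a single peak estimates the ICP/DCP merge locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .core import LayerModel
from .density import DepthDensityProfile


@dataclass
class Peak:
    plane: int
    height: float
    prominence: float
    label: str = "unassigned"


@dataclass
class PlexusFindings:
    """Peaks and troughs of one depth profile, with plexus assignments."""

    region: str
    peaks: list[Peak]
    troughs: list[Peak]
    profile: DepthDensityProfile | None = None
    bands: dict[str, tuple[float, float]] = field(default_factory=dict)
    dvc_peak_count: int | None = None

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.peaks]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "region": self.region,
                "kind": "peak",
                "plane": p.plane,
                "height": p.height,
                "prominence": p.prominence,
                "label": p.label,
            }
            for p in self.peaks
        ]
        rows += [
            {
                "region": self.region,
                "kind": "trough",
                "plane": t.plane,
                "height": t.height,
                "prominence": np.nan,
                "label": "",
            }
            for t in self.troughs
        ]
        return pd.DataFrame(
            rows, columns=["region", "kind", "plane", "height", "prominence", "label"]
        )


def find_peaks_troughs(
    profile: DepthDensityProfile, min_prominence: float = 0.02
) -> PlexusFindings:
    """Local maxima with prominence >= ``min_prominence``; troughs between them.

    The default prominence (2% density) sits above the phantom noise floor
    and below the smallest real plexus peak.  A flat profile yields zero
    peaks without error; absent planes count as zero density.
    """
    d = np.nan_to_num(profile.density, nan=0.0)
    if d.size < 5:
        raise ValueError("profile too short for peak detection (need >= 5 planes)")
    idx, props = _scipy_find_peaks(d, prominence=min_prominence)
    peaks = [
        Peak(int(i), float(d[i]), float(p)) for i, p in zip(idx, props["prominences"])
    ]
    troughs = []
    for a, b in zip(idx[:-1], idx[1:]):
        j = a + int(np.argmin(d[a : b + 1]))
        troughs.append(Peak(int(j), float(d[j]), 0.0, label="trough"))
    return PlexusFindings(region=profile.region, peaks=peaks, troughs=troughs, profile=profile)


def _window_bands(layers: LayerModel, window) -> dict[str, tuple[float, float]]:
    sx, sy = window
    m = {k: float(layers.surface(k)[sx, sy].mean()) for k in layers.surfaces}
    gcc80 = m["ILM"] + 0.8 * (m["IPL/INL"] - m["ILM"])
    inl50 = 0.5 * (m["IPL/INL"] + m["INL/OPL"])
    return {
        "RPCP": (m["ILM"], m["NFL/GCL"]),
        "SVP": (m["NFL/GCL"], gcc80),
        "ICP": (gcc80, inl50),
        "DCP": (inl50, m["OPL/ONL"]),
        "DVC": (gcc80, m["OPL/ONL"]),
    }


def assign_plexus_labels(
    findings: PlexusFindings,
    layers: LayerModel,
    region: str | None = None,
    merged_if_single_dvc: bool | None = None,
) -> PlexusFindings:
    """Label each peak by the anatomic band containing its depth.

    Band edges are the layer surfaces averaged over the profile's sampling
    window.  A lone peak in the deep vascular complex band is labeled
    "ICP/DCP" in the peripheral region (where the plexuses have merged);
    elsewhere single DVC peaks keep their half-band label.  Labels are
    invariant to uniform rescaling of the profile heights.
    """
    if findings.profile is None:
        raise ValueError("findings carry no profile; cannot locate the sampling window")
    region = region or findings.region
    bands = _window_bands(layers, findings.profile.window)
    findings.bands = bands
    if merged_if_single_dvc is None:
        merged_if_single_dvc = region == "peripheral"
    dvc_lo, dvc_hi = bands["DVC"]
    dvc_peaks = [p for p in findings.peaks if dvc_lo <= p.plane < dvc_hi]
    findings.dvc_peak_count = len(dvc_peaks)
    for p in findings.peaks:
        p.label = "unassigned"
        for name in ("RPCP", "SVP", "ICP", "DCP"):
            lo, hi = bands[name]
            if lo <= p.plane < hi:
                p.label = name
                break
    if merged_if_single_dvc and len(dvc_peaks) == 1:
        dvc_peaks[0].label = "ICP/DCP"
    findings.region = region
    return findings


def estimate_merge_eccentricity(
    findings_list: list[PlexusFindings],
    min_eccentricity_mm: float = 1.0,
) -> tuple[float | None, bool]:
    """Smallest eccentricity beyond which the DVC holds exactly one peak.

    ``findings_list`` must be labeled findings whose profiles carry
    eccentricities spanning macula to periphery; windows closer to the
    fovea than ``min_eccentricity_mm`` (FAZ ring territory, where all
    plexuses converge) are ignored.  Returns ``(eccentricity or None,
    stable)``; with a non-monotone peak count the *last* transition is
    reported and ``stable`` is False.
    """
    usable = [
        f
        for f in findings_list
        if f.profile is not None
        and f.profile.eccentricity_mm is not None
        and f.profile.eccentricity_mm >= min_eccentricity_mm
        and f.dvc_peak_count is not None
    ]
    if len(usable) < 5:
        raise ValueError("need >= 5 labeled profiles spanning the macula-to-periphery axis")
    usable.sort(key=lambda f: f.profile.eccentricity_mm)
    ecc = np.array([f.profile.eccentricity_mm for f in usable])
    merged = np.array([f.dvc_peak_count == 1 for f in usable])
    if not merged[-1]:
        return None, True
    # smallest index from which everything outward is merged
    i = len(merged)
    while i > 0 and merged[i - 1]:
        i -= 1
    stable = bool(np.all(merged[i:]) and not np.any(merged[:i]))
    return float(ecc[i]), stable
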