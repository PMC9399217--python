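"""SUVmax / SUVpeak extraction from dynamic volumes with spherical VOIs.

Conventions
-----------
* Volume space is in mm with the origin at the corner of the first voxel;
  the center of voxel (i, j, k) sits at ((i+0.5)*sx, (j+0.5)*sy, (k+0.5)*sz).
* A voxel belongs to a sphere iff its center lies inside or on the
  boundary.
* SUV normalization is body-weight based: SUV = C[Bq/mL] * weight[g] /
  injected[Bq], in g/mL.
* SUVpeak is the mean over a fixed 1-cm-diameter sphere centered on the
  hottest voxel's center.  That sphere may extend beyond the parent VOI;
  if the volume edge clips it, the mean over the surviving voxels is
  returned and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import STRICT_VOI_DIAMETERS_MM
from .errors import EmptyVOIError, InvalidInputError

__all__ = [
    "ImageVolume",
    "SphereVOI",
    "SubjectRecord",
    "SUVSeries",
    "suv_normalize",
    "voi_voxels",
    "suv_max",
    "suv_peak",
    "suv_time_course",
]

VoiClass = Literal["affected-joint", "contralateral-joint", "blood-pool", "background"]

#: Diameter (mm) of the sphere averaged for SUVpeak.
SUV_PEAK_DIAMETER_MM = 10.0


@dataclass(frozen=True)
class ImageVolume:
    """A single reconstructed frame: activity concentration on a voxel grid.

    ``data`` is in Bq/mL unless ``units == "suv"``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    mid_time_min: float
    duration_s: float = 0.0
    decay_corrected: bool = True
    units: str = "Bq/mL"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise InvalidInputError("volume data must be 3-D")
        if not np.all(np.isfinite(data)):
            raise InvalidInputError("volume data must be finite")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InvalidInputError("voxel spacing must be positive on all 3 axes")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0  # mm^3 -> mL

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing_mm))


@dataclass(frozen=True)
class SphereVOI:
    """Spherical volume of interest, specified in mm in volume space."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    voi_class: VoiClass | str = "affected-joint"

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise InvalidInputError("VOI diameter must be positive")
        object.__setattr__(self, "center_mm",
                           tuple(float(c) for c in self.center_mm))

    def validate_strict(self) -> None:
        """Enforce the study's class-diameter convention: 5-cm joints,
        2-cm blood pool, 1-cm background."""
        expected = STRICT_VOI_DIAMETERS_MM.get(str(self.voi_class))
        if expected is None:
            raise InvalidInputError(f"unknown VOI class {self.voi_class!r}")
        if abs(self.diameter_mm - expected) > 1e-9:
            raise InvalidInputError(
                f"strict mode: class {self.voi_class!r} requires a "
                f"{expected:g}-mm diameter, got {self.diameter_mm:g}")


@dataclass(frozen=True)
class SubjectRecord:
    """Subject metadata needed for SUV normalization."""

    weight_kg: float
    injected_mbq: float
    injection_time_min: float = 0.0

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise InvalidInputError("weight must be positive")
        if self.injected_mbq <= 0:
            raise InvalidInputError("injected activity must be positive")


def suv_normalize(volume: ImageVolume, subject: SubjectRecord) -> ImageVolume:
    """Convert a Bq/mL volume to SUV (g/mL) units.

    SUV = concentration * weight(g) / injected(Bq).
    """
    if volume.units == "suv":
        return volume
    factor = subject.weight_kg * 1000.0 / (subject.injected_mbq * 1e6)
    return replace(volume, data=volume.data * factor, units="suv")


def _voxel_center_distance2(volume: ImageVolume, center_mm: Sequence[float]) -> np.ndarray:
    idx = [np.arange(n) for n in volume.data.shape]
    coords = [(ax + 0.5) * s for ax, s in zip(idx, volume.spacing_mm)]
    dx = coords[0] - center_mm[0]
    dy = coords[1] - center_mm[1]
    dz = coords[2] - center_mm[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)


def voi_voxels(volume: ImageVolume, voi: SphereVOI) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the sphere.

    Raises :class:`EmptyVOIError` if no voxel center is inside.
    """
    r2 = (voi.diameter_mm / 2.0) ** 2
    # tiny tolerance so centers exactly on the boundary are included
    mask = _voxel_center_distance2(volume, voi.center_mm) <= r2 * (1 + 1e-12)
    if not mask.any():
        raise EmptyVOIError(
            f"VOI {voi.voi_class} (d={voi.diameter_mm} mm at {voi.center_mm}) "
            "contains no voxel centers")
    return mask


def suv_max(volume: ImageVolume, voi: SphereVOI) -> float:
    """Maximum voxel value inside the VOI."""
    mask = voi_voxels(volume, voi)
    return float(volume.data[mask].max())


def suv_peak(volume: ImageVolume, voi: SphereVOI,
             peak_diameter_mm: float = SUV_PEAK_DIAMETER_MM,
             return_flags: bool = False):
    """Mean value within a 1-cm sphere centered on the hottest VOI voxel.

    The hottest voxel is the argmax within the VOI (ties broken by the
    lowest linear voxel index).  The peak sphere is centered on that
    voxel's center and may extend outside the parent VOI; voxels outside
    the volume are dropped and the result flagged as clipped.
    """
    mask = voi_voxels(volume, voi)
    vals = np.where(mask, volume.data, -np.inf)
    flat_idx = int(np.argmax(vals))  # first occurrence = lowest linear index
    ijk = np.unravel_index(flat_idx, volume.data.shape)
    center = tuple((i + 0.5) * s for i, s in zip(ijk, volume.spacing_mm))

    r = peak_diameter_mm / 2.0
    clipped = any(c - r < 0 or c + r > e
                  for c, e in zip(center, volume.extent_mm))
    peak_voi = SphereVOI(center_mm=center, diameter_mm=peak_diameter_mm,
                         voi_class=voi.voi_class)
    peak_mask = voi_voxels(volume, peak_voi)
    value = float(volume.data[peak_mask].mean())
    if return_flags:
        return value, {"clipped": clipped, "hot_voxel": tuple(map(int, ijk))}
    return value


@dataclass
class SUVSeries:
    """Per-class SUV time courses."""

    table: pd.DataFrame  # columns: voi_class, time_min, suv_max, suv_peak, mean, n_voxels
    peak_times: dict[str, float] = field(default_factory=dict)

    def for_class(self, voi_class: str) -> pd.DataFrame:
        return self.table[self.table["voi_class"] == voi_class].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def suv_time_course(frames: Sequence[ImageVolume], vois: Sequence[SphereVOI],
                    subject: SubjectRecord, strict: bool = False) -> SUVSeries:
    """SUVmax/SUVpeak per VOI class across a time-ordered frame sequence.

    Also records, per class, the frame mid-time at which SUVmax is
    maximal (e.g. the blood-pool peak time and the joint uptake peak).
    """
    times = [f.mid_time_min for f in frames]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise InvalidInputError("frames must be in strictly increasing time order")
    if strict:
        for voi in vois:
            voi.validate_strict()

    rows = []
    for frame in frames:
        suv_frame = suv_normalize(frame, subject)
        for voi in vois:
            mask = voi_voxels(suv_frame, voi)
            rows.append({
                "voi_class": str(voi.voi_class),
                "time_min": frame.mid_time_min,
                "suv_max": suv_max(suv_frame, voi),
                "suv_peak": suv_peak(suv_frame, voi),
                "mean": float(suv_frame.data[mask].mean()),
                "n_voxels": int(mask.sum()),
            })
    table = pd.DataFrame(rows)
    peak_times = {
        cls: float(sub.loc[sub["suv_max"].idxmax(), "time_min"])
        for cls, sub in table.groupby("voi_class")
    }
    return SUVSeries(table=table, peak_times=peak_times)
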