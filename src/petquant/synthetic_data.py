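"""Seeded synthetic dynamic-PET subjects.

Everything downstream — kinetic fitting, SUV extraction, dosimetry — is
exercised on data from this module, so it reproduces the statistical
structure those analyses assume:

* a tri-exponential bolus-shaped whole-blood input function whose
  sampled maximum on the dynamic grid falls at the first frame (1.5 min);
* per-organ %IA curves with rapid renal clearance, slow hepatobiliary
  uptake peaking late in the scan, bladder filling peaking near 60 min,
  and a slowly decreasing body remainder, summing to < 100 %IA;
* a voxel phantom with two 5-cm joint spheres (one "affected" with
  elevated uptake, one contralateral), an artery cylinder carrying the
  input function, and a low-uptake muscle background.

All randomness flows from a single integer seed through named
sub-streams, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    DYNAMIC_FRAME_TIMES_MIN,
    LATE_FRAME_TIME_MIN,
    WHOLE_BODY_FRAME_TIMES_MIN,
)
from .dosimetry import SourceOrganSeries
from .errors import GeometryError, InvalidInputError
from .image_quant import ImageVolume, SphereVOI, SubjectRecord
from .kinetics import TwoTissueParams, forward_2tc
from .tac import TimeActivityCurve

__all__ = [
    "AifModel",
    "SyntheticSubjectSpec",
    "SyntheticPhantom",
    "generate_aif",
    "generate_organ_percent_ia",
    "generate_dynamic_phantom",
    "default_joint_params",
    "write_phantom",
]


# --------------------------------------------------------------------------
# Input function
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AifModel:
    """Tri-exponential bolus input: C(t) = sum_i A_i exp(-r_i (t - d))
    for t >= d, zero before.

    The default has one positive and two negative amplitudes summing to
    zero, so the curve starts at 0, peaks shortly after the delay and
    decays; the defaults place the sampled maximum on the standard
    dynamic grid at the 1.5-min frame.
    """

    amplitudes: tuple[float, float, float] = (40000.0, -20000.0, -20000.0)
    rates: tuple[float, float, float] = (0.12, 1.2, 6.0)
    delay_min: float = 0.5

    def __post_init__(self):
        amps = tuple(float(a) for a in self.amplitudes)
        rates = tuple(float(r) for r in self.rates)
        if len(amps) != 3 or len(rates) != 3:
            raise InvalidInputError("AifModel needs 3 amplitudes and 3 rates")
        if any(r <= 0 for r in rates):
            raise InvalidInputError("all AIF rates must be positive")
        if any(a != 0 for a in amps) and amps[0] <= 0:
            raise InvalidInputError("leading AIF amplitude must be positive")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "rates", rates)
        # non-negativity on [0, inf): checked on a dense grid
        t = np.linspace(self.delay_min, self.delay_min + 300.0, 4096)
        if np.any(self._eval(t) < -1e-9 * max(abs(a) for a in amps + (1.0,))):
            raise InvalidInputError("AIF model is negative somewhere on [0, inf)")

    def _eval(self, t: np.ndarray) -> np.ndarray:
        tau = np.asarray(t, dtype=float) - self.delay_min
        out = np.zeros_like(tau)
        pos = tau >= 0
        for a, r in zip(self.amplitudes, self.rates):
            out[pos] += a * np.exp(-r * tau[pos])
        return out

    def dense_curve(self, t_max_min: float = 50.0, step_min: float = 0.05) -> TimeActivityCurve:
        """Finely, uniformly sampled curve for use as a forward-model
        input (a uniform grid keeps the convolution recurrence fast)."""
        n = int(round(t_max_min / step_min))
        denom = round(1.0 / step_min)
        # integer-ratio times so common frame mid-times (1.5, 10.5, ...)
        # are hit exactly and no near-duplicate knots arise downstream
        grid = np.arange(n + 1) / denom if denom >= 1 else np.arange(n + 1) * step_min
        return TimeActivityCurve(times=grid, values=np.clip(self._eval(grid), 0.0, None))


def generate_aif(model: AifModel, times: Sequence[float]) -> TimeActivityCurve:
    """Sample the blood input model at the given times (min)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(t < 0):
        raise InvalidInputError("times must be non-negative")
    return TimeActivityCurve(times=t, values=np.clip(model._eval(t), 0.0, None))


# --------------------------------------------------------------------------
# Subject spec
# --------------------------------------------------------------------------

#: Default organ %IA kinetics (decay-corrected %IA).  Most organs follow a
#: normalized bateman shape amp * (e^{-a t} - e^{-b t}) scaled to peak at
#: ``amp``; washout organs peak before the first whole-body frame, the
#: bladder fills to ~60 min, the liver combines an early perfusion
#: plateau with a slow uptake component peaking near 80 min, and the
#: remainder decays slowly from ~76 %IA.
DEFAULT_ORGAN_KINETICS: dict[str, dict[str, float]] = {
    "brain":   {"amp": 2.35, "a": 0.006, "b": 0.065},
    "lung":    {"amp": 5.15, "a": 0.0136, "b": 2.0},
    "heart":   {"amp": 4.30, "a": 0.013, "b": 2.2},
    "kidney":  {"amp": 4.60, "a": 0.0125, "b": 1.8},
    "liver":   {"amp": 6.60, "a": 0.0016, "b": 0.040,
                "base_amp": 3.0, "base_rate": 0.0002},
    "bladder": {"amp": 8.00, "a": 0.003, "b": 0.05},
    "remainder": {"base_amp": 58.0, "amp": 19.0, "a": 1.0 / 55.0},
}

ORGANS = ("brain", "lung", "heart", "liver", "kidney", "bladder", "remainder")


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Reproducible description of one synthetic subject.

    Defaults mirror the acquisition this package targets: six whole-body
    frames at ~3-81 min for dosimetry and a 9-frame dynamic series
    (1.5-25 min) plus a ~45-min late point for joint quantification;
    injected activity and weight at the cohort means.
    """

    seed: int = 0
    weight_kg: float = 84.0
    injected_mbq: float = 614.5
    frame_times_min: tuple[float, ...] = WHOLE_BODY_FRAME_TIMES_MIN
    frame_durations_s: tuple[float, ...] = (60.0, 60.0, 120.0, 120.0, 180.0, 180.0)
    dynamic_times_min: tuple[float, ...] = DYNAMIC_FRAME_TIMES_MIN + (LATE_FRAME_TIME_MIN,)
    dynamic_durations_s: tuple[float, ...] = (90.0, 90.0, 120.0, 120.0, 240.0,
                                              180.0, 180.0, 180.0, 420.0, 300.0)
    joint_contrast: float = 1.5
    background_contrast: float = 6.0
    noise_scale: float = 0.05
    organ_kinetics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ORGAN_KINETICS)
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if int(self.seed) != self.seed:
            raise InvalidInputError("seed must be an integer")
        if self.weight_kg <= 0:
            raise InvalidInputError("weight must be positive")
        if self.injected_mbq <= 0:
            raise InvalidInputError("injected activity must be positive")
        for name in ("frame_times_min", "dynamic_times_min"):
            t = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing")
        if len(self.frame_durations_s) != len(self.frame_times_min):
            raise InvalidInputError("frame_durations_s length mismatch")
        if len(self.dynamic_durations_s) != len(self.dynamic_times_min):
            raise InvalidInputError("dynamic_durations_s length mismatch")
        if self.joint_contrast < 1.0:
            raise InvalidInputError("joint_contrast must be >= 1")
        if self.background_contrast <= 0:
            raise InvalidInputError("background_contrast must be positive")
        if self.noise_scale < 0:
            raise InvalidInputError("noise_scale must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, seed-derived pseudo-random stream."""
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF,
                                     int.from_bytes(stream.encode(), "little") % (2 ** 31)])
        return np.random.default_rng(ss)

    def subject_record(self) -> SubjectRecord:
        return SubjectRecord(weight_kg=self.weight_kg, injected_mbq=self.injected_mbq)


def default_joint_params() -> tuple[TwoTissueParams, TwoTissueParams]:
    """Default (affected, contralateral) joint kinetics.

    A slowly reversible trapping profile whose tissue curve rises
    monotonically over the 1.5-25-min dynamic grid, peaks at the 25-min
    frame and has declined by the ~45-min late frame.  The contralateral
    joint uses the same shape; the affected joint is scaled up by the
    spec's ``joint_contrast``.
    """
    base = TwoTissueParams(K1=0.30, k2=0.20, k3=0.50, k4=0.02, vB=0.05)
    return base, base


# --------------------------------------------------------------------------
# Organ %IA curves
# --------------------------------------------------------------------------

def _bateman(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """(e^{-a t} - e^{-b t}) normalized to peak at 1 (requires b > a)."""
    t_peak = np.log(b / a) / (b - a)
    denom = np.exp(-a * t_peak) - np.exp(-b * t_peak)
    return (np.exp(-a * t) - np.exp(-b * t)) / denom


def _organ_curve(organ: str, t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    if organ == "remainder":
        return p["base_amp"] + p["amp"] * np.exp(-p["a"] * t)
    curve = p["amp"] * _bateman(t, p["a"], p["b"])
    if "base_amp" in p:
        curve = curve + p["base_amp"] * np.exp(-p.get("base_rate", 0.0) * t)
    return curve


def generate_organ_percent_ia(spec: SyntheticSubjectSpec) -> list[SourceOrganSeries]:
    """Per-organ decay-corrected %IA series on the whole-body schedule.

    Noise is Gaussian with variance proportional to mean over frame
    duration (a counting-statistics proxy), truncated at zero; the total
    over organs stays <= 100 %IA by construction of the defaults.
    """
    t = np.asarray(spec.frame_times_min, dtype=float)
    dur_min = np.asarray(spec.frame_durations_s, dtype=float) / 60.0
    rng = spec.rng("organ-percent-ia")
    out = []
    for organ in ORGANS:
        params = spec.organ_kinetics[organ]
        mean = _organ_curve(organ, t, params)
        if spec.noise_scale > 0:
            sd = spec.noise_scale * np.sqrt(np.clip(mean, 0.0, None) / dur_min)
            values = np.clip(mean + rng.normal(0.0, 1.0, size=t.size) * sd, 0.0, None)
        else:
            sd = np.zeros_like(mean)
            values = np.clip(mean, 0.0, None)
        out.append(SourceOrganSeries(organ=organ, times=t, percent_ia=values,
                                     sd=sd if spec.noise_scale > 0 else None,
                                     decay_corrected=True))
    return out


# --------------------------------------------------------------------------
# Dynamic phantom
# --------------------------------------------------------------------------

@dataclass
class SyntheticPhantom:
    """Dynamic voxel phantom with labelled regions and their ground truth."""

    frames: list[ImageVolume]
    labels: dict[str, np.ndarray]            # region name -> boolean mask
    region_tacs: dict[str, TimeActivityCurve]
    subject: SubjectRecord
    spacing_mm: tuple[float, float, float]
    region_centers_mm: dict[str, tuple[float, float, float]]

    def vois(self) -> list[SphereVOI]:
        """Study-convention VOIs: 5-cm joints, 2-cm blood pool, 1-cm
        background, centered on the generating regions."""
        return [
            SphereVOI(self.region_centers_mm["affected-joint"], 50.0, "affected-joint"),
            SphereVOI(self.region_centers_mm["contralateral-joint"], 50.0,
                      "contralateral-joint"),
            SphereVOI(self.region_centers_mm["blood-pool"], 20.0, "blood-pool"),
            SphereVOI(self.region_centers_mm["background"], 10.0, "background"),
        ]


def _sphere_mask(shape, spacing, center_mm, diameter_mm):
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    d2 = ((coords[0] - center_mm[0])[:, None, None] ** 2
          + (coords[1] - center_mm[1])[None, :, None] ** 2
          + (coords[2] - center_mm[2])[None, None, :] ** 2)
    return d2 <= (diameter_mm / 2.0) ** 2 * (1 + 1e-12)


def _cylinder_mask(shape, spacing, center_xy_mm, radius_mm, z_range_mm):
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    d2 = ((coords[0] - center_xy_mm[0])[:, None] ** 2
          + (coords[1] - center_xy_mm[1])[None, :] ** 2)
    in_xy = d2 <= radius_mm ** 2
    in_z = (coords[2] >= z_range_mm[0]) & (coords[2] <= z_range_mm[1])
    return in_xy[:, :, None] & in_z[None, None, :]


def generate_dynamic_phantom(
    spec: SyntheticSubjectSpec,
    truth: tuple[TwoTissueParams, TwoTissueParams] | None = None,
    aif: AifModel | None = None,
) -> SyntheticPhantom:
    """Build a dynamic phantom on the spec's dynamic frame schedule.

    Region activity concentrations (Bq/mL):

    * ``affected-joint`` / ``contralateral-joint``: forward 2TC curves.
      With ``truth=None`` both joints share :func:`default_joint_params`
      and the affected joint is scaled by ``spec.joint_contrast``; with
      an explicit (affected, contralateral) pair the two models are used
      directly and no extra scaling is applied.
    * ``blood-pool``: the input function itself (an artery cylinder).
    * ``background``: the affected-joint curve divided by
      ``spec.background_contrast`` (unlabelled muscle everywhere else at
      the same level).

    Noise, when ``spec.noise_scale > 0``, is voxelwise Gaussian with
    variance proportional to local mean over frame duration, truncated
    at zero.
    """
    if aif is None:
        aif = AifModel()
    times = np.asarray(spec.dynamic_times_min, dtype=float)
    durations = np.asarray(spec.dynamic_durations_s, dtype=float)
    # the input the phantom "sees" is the image-derived blood curve at
    # the frame times (zero before the first frame, linear between), so
    # fitting the extracted joint TACs against the extracted artery TAC
    # is exactly self-consistent
    input_curve = generate_aif(aif, times)

    scaled = truth is None
    if truth is None:
        affected_p, contra_p = default_joint_params()
    else:
        affected_p, contra_p = truth

    contra_tac = forward_2tc(contra_p, input_curve, times)
    affected_tac = forward_2tc(affected_p, input_curve, times)
    if scaled:
        affected_tac = TimeActivityCurve(
            times=times, values=affected_tac.values * spec.joint_contrast,
            decay_corrected=affected_tac.decay_corrected)
    blood_tac = TimeActivityCurve(times=times, values=input_curve.interp(times))
    background_tac = TimeActivityCurve(
        times=times, values=affected_tac.values / spec.background_contrast,
        decay_corrected=affected_tac.decay_corrected)

    shape = tuple(int(n) for n in spec.volume_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing_mm)
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    # geometry: joints side by side in x, artery behind in y, background
    # sphere in free muscle.  Region centers snap to voxel centers so the
    # two joints are congruent on the lattice (identical voxelization).
    joint_r = 25.0
    artery_r = 16.0  # wide enough that a 1-cm peak sphere inside the
    #                  2-cm blood VOI never leaves the blood region

    def snap(c_mm: float, axis: int) -> float:
        i = round(c_mm / spacing[axis] - 0.5)
        return (i + 0.5) * spacing[axis]

    def snapped(fractions):
        return tuple(snap(f * extent[ax], ax) for ax, f in enumerate(fractions))

    centers = {
        "affected-joint": snapped((0.25, 0.35, 0.5)),
        "contralateral-joint": snapped((0.75, 0.35, 0.5)),
        "blood-pool": snapped((0.5, 0.75, 0.5)),
        "background": snapped((0.15, 0.85, 0.5)),
    }
    for name, c in centers.items():
        r = {"affected-joint": joint_r, "contralateral-joint": joint_r,
             "blood-pool": artery_r, "background": 10.0}[name]
        if any(ci - r < 0 or ci + r > e for ci, e in zip(c, extent)):
            raise GeometryError(
                f"volume {shape} at spacing {spacing} too small to hold region {name}")
    # the joints must clear each other by a full 1-cm peak-sphere
    # diameter so a peak sphere seeded in one VOI cannot sample the other
    gap = (centers["contralateral-joint"][0] - centers["affected-joint"][0]
           - 2.0 * joint_r)
    if gap < 10.0:
        raise GeometryError(
            f"volume {shape} at spacing {spacing} leaves only {gap:.1f} mm "
            "between the joint spheres (need >= 10 mm)")

    masks = {
        "affected-joint": _sphere_mask(shape, spacing, centers["affected-joint"], 50.0),
        "contralateral-joint": _sphere_mask(shape, spacing,
                                            centers["contralateral-joint"], 50.0),
        "blood-pool": _cylinder_mask(
            shape, spacing, (centers["blood-pool"][0], centers["blood-pool"][1]),
            artery_r, (0.1 * extent[2], 0.9 * extent[2])),
    }
    overlap = (masks["affected-joint"].astype(int)
               + masks["contralateral-joint"].astype(int)
               + masks["blood-pool"].astype(int))
    if int(overlap.max()) > 1:
        raise GeometryError("phantom regions overlap; enlarge the volume")
    muscle = ~(masks["affected-joint"] | masks["contralateral-joint"]
               | masks["blood-pool"])
    masks["background"] = muscle

    region_tacs = {
        "affected-joint": affected_tac,
        "contralateral-joint": contra_tac,
        "blood-pool": blood_tac,
        "background": background_tac,
    }

    rng = spec.rng("phantom-noise")
    frames: list[ImageVolume] = []
    for i, (t, dur) in enumerate(zip(times, durations)):
        vol = np.full(shape, background_tac.values[i], dtype=float)
        vol[masks["affected-joint"]] = affected_tac.values[i]
        vol[masks["contralateral-joint"]] = contra_tac.values[i]
        vol[masks["blood-pool"]] = blood_tac.values[i]
        if spec.noise_scale > 0:
            sd = spec.noise_scale * np.sqrt(np.clip(vol, 0.0, None) / (dur / 60.0))
            vol = np.clip(vol + rng.normal(size=shape) * sd, 0.0, None)
        frames.append(ImageVolume(data=vol, spacing_mm=spacing, mid_time_min=float(t),
                                  duration_s=float(dur), decay_corrected=True))

    return SyntheticPhantom(frames=frames, labels=masks, region_tacs=region_tacs,
                            subject=spec.subject_record(), spacing_mm=spacing,
                            region_centers_mm=centers)


# --------------------------------------------------------------------------
# On-disk output
# --------------------------------------------------------------------------

def write_phantom(phantom: SyntheticPhantom, out_dir: str | Path) -> dict:
    """Write one NIfTI volume per frame plus a JSON sidecar; returns the
    sidecar document."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.spacing_mm) + [1.0])
    frame_files = []
    for i, frame in enumerate(phantom.frames):
        fname = f"frame_{i:02d}.nii"
        nib.Nifti1Image(frame.data.astype(np.float32), affine).to_filename(out / fname)
        frame_files.append(fname)
    sidecar = {
        "frame_files": frame_files,
        "frame_mid_times_min": [f.mid_time_min for f in phantom.frames],
        "frame_durations_s": [f.duration_s for f in phantom.frames],
        "injected_activity_mbq": phantom.subject.injected_mbq,
        "weight_kg": phantom.subject.weight_kg,
        "decay_corrected": all(f.decay_corrected for f in phantom.frames),
        "voxel_spacing_mm": list(phantom.spacing_mm),
        "region_centers_mm": {k: list(v) for k, v in phantom.region_centers_mm.items()},
    }
    (out / "frames.json").write_text(json.dumps(sidecar, indent=2))
    for name, tac in phantom.region_tacs.items():
        tac.to_csv(out / f"tac_{name}.csv")
    return sidecar
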