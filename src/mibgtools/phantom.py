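"""Synthetic early/late mIBG studies: LV shell phantoms and cohorts.

No patient images are deposited with the study this package models, so every
downstream stage is exercised on phantoms: a half-ellipsoid left-ventricular
shell (closed apex, open base) voxelised on a regular grid, with a known
tracer concentration per AHA segment at each of two time points (15 min and
4 h post injection), a uniform extracardiac background, and optional
voxel-wise Poisson counting noise.  Anterior planar scintigrams are produced
by summing the (possibly noisy) volume along the anterior-posterior axis and
adding a mediastinal background band, so planar noise arises from a single
noise application in the volume.

Ground truth (per-segment normalised uptake and washout) is computed from
the noise-free activity field, never from sampled counts.

Default activity levels are chosen to resemble a 370 MBq 123I-mIBG
acquisition summed over a clinical scan duration: several hundred expected
counts per wall voxel, heart-to-background concentration well above one, and
a late/early wall ratio near 0.73 (a global washout in the mid-20 % range).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .planar import PlanarScan, RoiSpec, mediastinum_box_roi
from .polar import LvAxis, LvVolume, SegmentProfile, WashoutMap, segment_of
from .stats import PatientRecord

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "CohortSpec",
    "GeometryError",
    "make_phantom",
    "planar_project",
    "mediastinum_band_mask",
    "make_cohort",
]


class GeometryError(ValueError):
    """The requested LV shell has no voxels on the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic early/late study.

    Activities are expected counts per voxel.  The LV long axis runs along
    the third grid axis (k), base at ``lv_center`` toward +k; the anterior
    direction (projection axis and angular reference) is +i.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    lv_center: tuple[float, float, float] = (24.0, 24.0, 10.0)
    lv_radii_mm: tuple[float, float, float] = (30.0, 30.0, 50.0)
    wall_thickness_mm: float = 10.0
    segment_activity_early: tuple[float, ...] = (800.0,) * 17
    segment_activity_late: tuple[float, ...] = (584.0,) * 17
    background_activity: float = 40.0
    mediastinum_activity: float = 6.0
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("segment_activity_early", "segment_activity_late"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (17,) or np.any(arr < 0):
                raise ValueError(f"{name} must be 17 nonnegative values")
        if self.background_activity < 0 or self.mediastinum_activity < 0:
            raise ValueError("background activities must be nonnegative")
        if self.wall_thickness_mm >= min(self.lv_radii_mm):
            raise ValueError("wall thickness must be below the smallest LV radius")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


@dataclass
class PhantomStudy:
    """One generated study with its noise-free ground truth."""

    spec: PhantomSpec
    planar_early: PlanarScan
    planar_late: PlanarScan
    volume_early: LvVolume
    volume_late: LvVolume
    truth_uptake_early: SegmentProfile
    truth_uptake_late: SegmentProfile
    truth_washout: WashoutMap
    segment_labels: np.ndarray
    mediastinum_roi: RoiSpec


def _shell_labels(spec: PhantomSpec) -> np.ndarray:
    """Geometric segment membership (0 outside, 1..17 in-wall) of the
    half-ellipsoid shell, evaluated at voxel centres."""
    vs = np.asarray(spec.voxel_size_mm, dtype=float)
    center = np.asarray(spec.lv_center, dtype=float) * vs
    a, b, c = spec.lv_radii_mm
    w = spec.wall_thickness_mm
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.grid_shape, vs)], indexing="ij"
    )
    p = np.stack(grids, axis=-1) - center
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    outer = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    inner = (x / (a - w)) ** 2 + (y / (b - w)) ** 2 + (z / (c - w)) ** 2
    shell = (outer <= 1.0) & (inner >= 1.0) & (z >= 0.0)
    t = z / c
    theta = np.degrees(np.arctan2(y, x))  # anterior=+i, w-axis=+j for +k axis
    labels = segment_of(t, theta)
    labels[~shell] = 0
    return labels


def _axis(spec: PhantomSpec) -> LvAxis:
    apex = (
        spec.lv_center[0],
        spec.lv_center[1],
        spec.lv_center[2] + spec.lv_radii_mm[2] / spec.voxel_size_mm[2],
    )
    return LvAxis(base=spec.lv_center, apex=apex, angular_reference=(1.0, 0.0, 0.0))


def _band_corner(spec: PhantomSpec) -> tuple[int, int]:
    nj, nk = spec.grid_shape[1], spec.grid_shape[2]
    apex_k = int(np.ceil(spec.lv_center[2] + spec.lv_radii_mm[2] / spec.voxel_size_mm[2]))
    return nj // 3, min(nk - 1, apex_k + 2)


def mediastinum_band_mask(spec: PhantomSpec) -> np.ndarray:
    """Pixel mask of the mediastinal band on the projected (j, k) image:
    a midline box clear of the projected LV, beyond the apex rows."""
    nj, nk = spec.grid_shape[1], spec.grid_shape[2]
    j0, k0 = _band_corner(spec)
    mask = np.zeros((nj, nk), dtype=bool)
    mask[j0:2 * nj // 3, k0:nk] = True
    if not mask.any():
        raise GeometryError("no room for the mediastinal band above the apex")
    return mask


def planar_project(
    volume: LvVolume,
    background_model: PhantomSpec | None = None,
    rng: np.random.Generator | None = None,
) -> PlanarScan:
    """Anterior planar image: counts summed along the anterior-posterior
    (first) axis, plus a mediastinal band when a background model is given.

    Band expectation per pixel is ``mediastinum_activity`` times the grid
    depth (a column of tissue at that concentration); Poisson noise is
    applied to the band when the model requests it and an ``rng`` is given.
    """
    if volume.counts.size == 0:
        raise ValueError("cannot project an empty volume")
    image = volume.counts.sum(axis=0)
    pixel_size = (volume.voxel_size_mm[1], volume.voxel_size_mm[2])
    if background_model is not None:
        band = mediastinum_band_mask(background_model)
        expectation = background_model.mediastinum_activity * background_model.grid_shape[0]
        if background_model.noise == "poisson" and rng is not None:
            image = image + band * rng.poisson(expectation, size=band.shape)
        else:
            image = image + band * expectation
    return PlanarScan(counts=image, pixel_size_mm=pixel_size, timepoint=volume.timepoint)


def make_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Generate one paired early/late study from a phantom specification.

    Deterministic for a fixed spec (the seed drives all noise).  Raises
    :class:`GeometryError` when the shell voxelises to nothing.
    """
    labels = _shell_labels(spec)
    if not (labels > 0).any():
        raise GeometryError("LV shell is empty on this grid; check radii/center")
    axis = _axis(spec)
    rng = np.random.default_rng(spec.seed)

    act_e = np.asarray(spec.segment_activity_early, dtype=float)
    act_l = np.asarray(spec.segment_activity_late, dtype=float)
    volumes = {}
    for tp, act in (("early_15min", act_e), ("late_4h", act_l)):
        expect = np.full(spec.grid_shape, spec.background_activity, dtype=float)
        wall = labels > 0
        expect[wall] = act[labels[wall] - 1]
        counts = rng.poisson(expect).astype(float) if spec.noise == "poisson" else expect
        volumes[tp] = LvVolume(
            counts=counts, voxel_size_mm=spec.voxel_size_mm, axis=axis, timepoint=tp
        )

    planar = {
        tp: planar_project(volumes[tp], background_model=spec, rng=rng)
        for tp in ("early_15min", "late_4h")
    }

    # Ground truth from the activity field: with uniform concentration per
    # segment the top-decile mean equals the concentration itself.
    truth_e = SegmentProfile(100.0 * act_e / act_e.max(), timepoint="early_15min")
    truth_l = SegmentProfile(100.0 * act_l / act_l.max(), timepoint="late_4h")
    # H/M-ready mediastinal ROI: standardised ~1,200 mm^2 box inside the band.
    med_roi = mediastinum_box_roi(planar["late_4h"], corner=_band_corner(spec))
    return PhantomStudy(
        spec=spec,
        planar_early=planar["early_15min"],
        planar_late=planar["late_4h"],
        volume_early=volumes["early_15min"],
        volume_late=volumes["late_4h"],
        truth_uptake_early=truth_e,
        truth_uptake_late=truth_l,
        truth_washout=WashoutMap(truth_e.values - truth_l.values),
        segment_labels=labels,
        mediastinum_roi=med_roi,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Bernoulli model linking post-PVI deficit status to AF relapse.

    Defaults mirror the study structure: 16 patients, 62.5 % post-PVI
    deficit prevalence, relapse probability 0.4 given a deficit and 0.167
    without one.
    """

    n_patients: int = 16
    p_defect: float = 0.625
    p_relapse_given_defect: float = 0.4
    p_relapse_given_no_defect: float = 0.167
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("p_defect", "p_relapse_given_defect", "p_relapse_given_no_defect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a synthetic cohort with ground-truth deficit and relapse labels.

    Labels are independent per patient: defect ~ Bernoulli(p_defect), then
    relapse ~ Bernoulli(p_relapse_given_defect or _no_defect).  Demographics
    are drawn to resemble a paroxysmal-AF referral population (age 40-72,
    about two-thirds male) and carry no information about the labels.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n_patients):
        defect = bool(rng.random() < spec.p_defect)
        p_rel = spec.p_relapse_given_defect if defect else spec.p_relapse_given_no_defect
        relapse = bool(rng.random() < p_rel)
        cohort.append(
            PatientRecord(
                id=i + 1,
                sex="M" if rng.random() < 11 / 16 else "F",
                age=float(np.clip(np.round(rng.normal(57, 9)), 40, 72)),
                af_duration=float(max(1, np.round(rng.exponential(5)))),
                la_volume_ml=float(np.round(np.clip(rng.normal(105, 30), 40, 200))),
                relapse=relapse,
                defect_post=defect,
            )
        )
    return cohort
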