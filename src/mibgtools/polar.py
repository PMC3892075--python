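"""Mapping of left-ventricular count volumes onto the AHA 17-segment model.

The left ventricle is summarised regionally on the standard 17-segment
partition: six basal and six mid-cavity 60-degree sectors, four apical
90-degree sectors, and the apical cap.  Segment membership is computed from a
fixed polar geometry around a user-supplied long axis; segmental uptake is the
mean of the top decile of wall-voxel counts in each segment (a radial-maximum
-like statistic that is robust to wall-thickness variation), expressed as a
percentage of the hottest segment.  Regional washout is the early-minus-late
difference of those normalised uptakes, in percentage points.

Geometry convention (stated once, used everywhere, including the phantom
generator): the short-axis angle theta is measured from the anterior reference
direction and increases anterior -> septal -> inferior -> lateral; the long
axis runs base -> apex, the apical cap is the most apical 15 % of the axis and
the remaining 85 % is split into three equal basal/mid/apical bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEGMENT_NAMES",
    "APICAL_CAP_FRACTION",
    "LvAxis",
    "LvVolume",
    "SegmentProfile",
    "WashoutMap",
    "EmptySegmentError",
    "segment_of",
    "assign_segments",
    "sample_segments",
    "normalize_uptake",
    "segmental_washout",
    "profile_chain",
]

#: AHA segment names, 1-based.
SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}

#: Fraction of the long axis (apical end) assigned to segment 17.
APICAL_CAP_FRACTION = 0.15


class EmptySegmentError(ValueError):
    """A segment received no labeled voxels and cannot be sampled."""


@dataclass(frozen=True)
class LvAxis:
    """Long-axis specification of an LV volume, in voxel coordinates.

    ``base`` and ``apex`` are points in (i, j, k) voxel coordinates;
    ``angular_reference`` is a direction (in millimetre space) whose
    projection onto the short-axis plane defines the anterior sector centre.
    """

    base: tuple[float, float, float]
    apex: tuple[float, float, float]
    angular_reference: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if np.allclose(self.base, self.apex):
            raise ValueError("LV axis is degenerate: apex equals base")

    def frame_mm(self, voxel_size_mm) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
        """Return (origin, axis_dir, u, w, length) in millimetre space.

        ``u`` points toward the anterior reference, ``w`` completes the
        right-handed short-axis basis so atan2(p.w, p.u) increases
        anterior -> septal -> inferior -> lateral.
        """
        vs = np.asarray(voxel_size_mm, dtype=float)
        base = np.asarray(self.base, dtype=float) * vs
        apex = np.asarray(self.apex, dtype=float) * vs
        d = apex - base
        length = float(np.linalg.norm(d))
        dirv = d / length
        ref = np.asarray(self.angular_reference, dtype=float)
        u = ref - np.dot(ref, dirv) * dirv
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ValueError("angular_reference is parallel to the long axis")
        u = u / nu
        w = np.cross(dirv, u)
        return base, dirv, u, w, length


@dataclass
class LvVolume:
    """A 3-D count volume with voxel size and LV long-axis specification."""

    counts: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    axis: LvAxis
    timepoint: str = "late_4h"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel sizes must be positive")


@dataclass
class SegmentProfile:
    """17 normalised uptake values in percent of the hottest segment."""

    values: np.ndarray
    timepoint: str = "late_4h"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (17,):
            raise ValueError("a segment profile has exactly 17 values")


@dataclass
class WashoutMap:
    """Early-minus-late normalised uptake, in percentage points (signed)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (17,):
            raise ValueError("a washout map has exactly 17 values")


def segment_of(t, theta_deg, cap_fraction: float = APICAL_CAP_FRACTION):
    """Segment id (1-17) from normalised long-axis position and angle.

    ``t`` runs 0 at the base to 1 at the apex; ``theta_deg`` is measured from
    the anterior reference, increasing anterior -> septal -> inferior ->
    lateral.  Sectors are centred on their compass direction (the anterior
    sector spans -30..30 degrees basally/mid, -45..45 degrees apically).
    Vectorised over array inputs; positions with t outside [0, 1] map to 0.
    """
    t = np.asarray(t, dtype=float)
    theta = np.mod(np.asarray(theta_deg, dtype=float), 360.0)
    seg = np.zeros(np.broadcast(t, theta).shape, dtype=np.int16)
    inside = (t >= 0.0) & (t <= 1.0)
    cap = inside & (t >= 1.0 - cap_fraction)
    band_len = (1.0 - cap_fraction) / 3.0
    band = np.floor_divide(t, band_len).astype(int)  # 0 basal, 1 mid, 2 apical
    sector6 = np.floor_divide(np.mod(theta + 30.0, 360.0), 60.0).astype(int)
    sector4 = np.floor_divide(np.mod(theta + 45.0, 360.0), 90.0).astype(int)
    seg = np.where(inside & (band == 0), 1 + sector6, seg)
    seg = np.where(inside & (band == 1), 7 + sector6, seg)
    seg = np.where(inside & (band == 2), 13 + sector4, seg)
    seg = np.where(cap, 17, seg)
    return seg.astype(np.int16)


def _polar_coordinates(volume: LvVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (t, theta_deg) relative to the volume's LV axis."""
    base, dirv, u, w, length = volume.axis.frame_mm(volume.voxel_size_mm)
    shape = volume.counts.shape
    vs = np.asarray(volume.voxel_size_mm, dtype=float)
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, vs)], indexing="ij"
    )
    p = np.stack(grids, axis=-1) - base
    t = p @ dirv / length
    theta = np.degrees(np.arctan2(p @ w, p @ u))
    return t, theta


def assign_segments(
    volume: LvVolume,
    wall_threshold: float | None = None,
    threshold_frac: float = 0.5,
) -> np.ndarray:
    """Label each voxel 0 (outside the wall) or with its segment id 1-17.

    Wall membership is by count threshold: voxels whose counts exceed
    ``wall_threshold`` (default ``threshold_frac`` times the volume's 99th
    percentile count) are taken as myocardium; each is then assigned the
    segment its polar coordinates fall in.

    Raises
    ------
    ValueError
        If no voxel is labeled (empty volume or threshold too high).
    """
    if wall_threshold is None:
        wall_threshold = threshold_frac * float(np.percentile(volume.counts, 99))
    wall = volume.counts > wall_threshold
    if not wall.any():
        raise ValueError("no voxel exceeds the wall-membership threshold")
    t, theta = _polar_coordinates(volume)
    labels = segment_of(t, theta)
    labels[~wall] = 0
    if not (labels > 0).any():
        raise ValueError(
            "no wall voxel falls inside the LV axis span; check the axis spec"
        )
    return labels


def sample_segments(
    volume: LvVolume, labels: np.ndarray, top_fraction: float = 0.1
) -> np.ndarray:
    """Raw per-segment counts: mean of the top ``top_fraction`` of voxels.

    Raises :class:`EmptySegmentError` naming the first segment with no
    labeled voxels.
    """
    if labels.shape != volume.counts.shape:
        raise ValueError("label field must be congruent with the volume")
    raw = np.empty(17, dtype=float)
    for s in range(1, 18):
        vals = volume.counts[labels == s]
        if vals.size == 0:
            raise EmptySegmentError(
                f"segment {s} ({SEGMENT_NAMES[s]}) has no labeled voxels"
            )
        k = max(1, math.ceil(top_fraction * vals.size))
        top = np.partition(vals, vals.size - k)[vals.size - k:]
        raw[s - 1] = float(top.mean())
    return raw


def normalize_uptake(raw: np.ndarray, timepoint: str = "late_4h") -> SegmentProfile:
    """Normalise raw segment counts to percent of the hottest segment."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (17,):
        raise ValueError("expected 17 raw segment values")
    peak = raw.max()
    if peak <= 0:
        raise ValueError("cannot normalise an all-zero uptake vector")
    return SegmentProfile(values=100.0 * raw / peak, timepoint=timepoint)


def segmental_washout(early: SegmentProfile, late: SegmentProfile) -> WashoutMap:
    """Regional washout: early minus late normalised uptake, per segment.

    Because each profile is self-normalised to its own maximum, washout can
    be negative in segments whose relative uptake rises between time points.
    """
    return WashoutMap(values=early.values - late.values)


def profile_chain(
    volume: LvVolume,
    wall_threshold: float | None = None,
    labels: np.ndarray | None = None,
) -> SegmentProfile:
    """Convenience: assign -> sample -> normalise for one volume."""
    if labels is None:
        labels = assign_segments(volume, wall_threshold=wall_threshold)
    raw = sample_segments(volume, labels)
    return normalize_uptake(raw, timepoint=volume.timepoint)
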