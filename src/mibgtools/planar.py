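"""Global planar metrics: heart-to-mediastinum ratio and washout rate.

On anterior planar scintigrams acquired early (15 min p.i.) and late (4 h
p.i.), the H/M ratio is the mean counts/pixel in a heart region of interest
divided by the mean counts/pixel in an upper-midline mediastinal ROI of
standardised physical area (1,200 mm^2).  The global washout rate is the
percentage loss of background-subtracted myocardial counts between the two
acquisitions; an optional physical-decay correction for 123-I (half-life
13.2232 h) is exposed behind a flag because reporting conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "IODINE123_HALF_LIFE_H",
    "MEDIASTINUM_AREA_MM2",
    "PlanarScan",
    "RoiSpec",
    "PlanarMetrics",
    "mean_counts",
    "hm_ratio",
    "washout_rate",
    "planar_metrics",
    "auto_heart_roi",
    "mediastinum_box_roi",
]

#: Physical half-life of iodine-123, hours.
IODINE123_HALF_LIFE_H = 13.2232

#: Standardised mediastinal ROI area, mm^2.
MEDIASTINUM_AREA_MM2 = 1200.0

#: Relative tolerance on the mediastinal ROI area (pixels rarely tile
#: 1,200 mm^2 exactly).
MEDIASTINUM_AREA_RTOL = 0.10

_DEFAULT_OFFSETS_H = {"early_15min": 0.25, "late_4h": 4.0}


@dataclass
class PlanarScan:
    """A 2-D planar count image with pixel size and time-point label."""

    counts: np.ndarray
    pixel_size_mm: tuple[float, float]
    timepoint: str
    acquisition_offset_h: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("a planar scan is a 2-D image")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.isscalar(self.pixel_size_mm):
            self.pixel_size_mm = (float(self.pixel_size_mm),) * 2
        if any(s <= 0 for s in self.pixel_size_mm):
            raise ValueError("pixel size must be positive")
        if self.timepoint not in _DEFAULT_OFFSETS_H:
            raise ValueError(
                f"timepoint must be one of {sorted(_DEFAULT_OFFSETS_H)}"
            )
        if self.acquisition_offset_h is None:
            self.acquisition_offset_h = _DEFAULT_OFFSETS_H[self.timepoint]

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_size_mm[0] * self.pixel_size_mm[1])


@dataclass
class RoiSpec:
    """A boolean pixel mask with a role label (heart or mediastinum)."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.label not in ("heart", "mediastinum"):
            raise ValueError("ROI label must be 'heart' or 'mediastinum'")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class PlanarMetrics:
    hm_early: float
    hm_late: float
    washout_rate_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "hm_early": self.hm_early,
            "hm_late": self.hm_late,
            "washout_rate_pct": self.washout_rate_pct,
        }


def _check_congruent(scan: PlanarScan, roi: RoiSpec) -> None:
    if roi.mask.shape != scan.counts.shape:
        raise ValueError("ROI mask is not congruent with the scan")


def _check_mediastinum_area(scan: PlanarScan, roi: RoiSpec) -> None:
    area = roi.mask.sum() * scan.pixel_area_mm2
    lo = MEDIASTINUM_AREA_MM2 * (1 - MEDIASTINUM_AREA_RTOL)
    hi = MEDIASTINUM_AREA_MM2 * (1 + MEDIASTINUM_AREA_RTOL)
    if not (lo <= area <= hi):
        raise ValueError(
            f"mediastinal ROI area {area:.0f} mm^2 outside the standardised "
            f"{MEDIASTINUM_AREA_MM2:.0f} mm^2 (+/-{MEDIASTINUM_AREA_RTOL:.0%})"
        )


def mean_counts(scan: PlanarScan, roi: RoiSpec) -> float:
    """Arithmetic mean counts/pixel over the ROI."""
    _check_congruent(scan, roi)
    return float(scan.counts[roi.mask].mean())


def hm_ratio(scan: PlanarScan, heart: RoiSpec, mediastinum: RoiSpec) -> float:
    """Heart-to-mediastinum ratio of mean counts/pixel.

    Raises if the mediastinal mean is zero (degenerate background) or the
    mediastinal ROI area is outside the standardised band.
    """
    if mediastinum.label == "mediastinum":
        _check_mediastinum_area(scan, mediastinum)
    m = mean_counts(scan, mediastinum)
    if m <= 0:
        raise ValueError("mediastinal mean counts are zero; H/M undefined")
    return mean_counts(scan, heart) / m


def washout_rate(
    early: PlanarScan,
    late: PlanarScan,
    heart: RoiSpec,
    mediastinum: RoiSpec,
    background_subtract: bool = True,
    decay_correct: bool = False,
    half_life_h: float = IODINE123_HALF_LIFE_H,
) -> float:
    """Global washout rate in percent.

    Default (background-subtracted, no decay correction):

        WR = 100 * [(He - Me) - (Hl - Ml)] / (He - Me)

    where H and M are heart/mediastinal ROI means on the early and late
    scans.  With ``decay_correct``, late means are first multiplied by
    2**(dt / half_life_h) with dt the early-to-late interval in hours.
    Raises on a nonpositive denominator rather than clamping.
    """
    if early.counts.shape != late.counts.shape:
        raise ValueError("early and late scans are not congruent")
    if mediastinum.label == "mediastinum":
        _check_mediastinum_area(early, mediastinum)
    he, hl = mean_counts(early, heart), mean_counts(late, heart)
    me, ml = mean_counts(early, mediastinum), mean_counts(late, mediastinum)
    if decay_correct:
        dt = late.acquisition_offset_h - early.acquisition_offset_h
        factor = 2.0 ** (dt / half_life_h)
        hl, ml = hl * factor, ml * factor
    num_early = he - me if background_subtract else he
    num_late = hl - ml if background_subtract else hl
    if num_early <= 0:
        raise ValueError(
            "nonpositive background-subtracted early heart counts; "
            "washout rate undefined"
        )
    return 100.0 * (num_early - num_late) / num_early


def planar_metrics(
    early: PlanarScan,
    late: PlanarScan,
    heart: RoiSpec,
    mediastinum: RoiSpec,
    **wr_options,
) -> PlanarMetrics:
    """H/M ratios at both time points plus the global washout rate."""
    return PlanarMetrics(
        hm_early=hm_ratio(early, heart, mediastinum),
        hm_late=hm_ratio(late, heart, mediastinum),
        washout_rate_pct=washout_rate(early, late, heart, mediastinum, **wr_options),
    )


def auto_heart_roi(scan: PlanarScan, threshold_frac: float = 0.5) -> RoiSpec:
    """Convenience heart ROI for phantoms: largest connected component of
    pixels above ``threshold_frac`` of the image maximum.

    The study's heart ROIs were visually drawn and are irreproducible; this
    automatic placement is intended for synthetic images only.
    """
    mask = scan.counts > threshold_frac * scan.counts.max()
    if not mask.any():
        raise ValueError("no pixel exceeds the heart-ROI threshold")
    lab = measure.label(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return RoiSpec(mask=lab == largest, label="heart")


def mediastinum_box_roi(
    scan: PlanarScan,
    corner: tuple[int, int],
    area_mm2: float = MEDIASTINUM_AREA_MM2,
) -> RoiSpec:
    """A fixed box ROI of approximately ``area_mm2`` with its low-index
    corner at ``corner``, filled row-major so the pixel count tiles the
    requested area as exactly as the grid allows."""
    n_pix = max(1, round(area_mm2 / scan.pixel_area_mm2))
    side = max(1, int(round(np.sqrt(n_pix))))
    mask = np.zeros_like(scan.counts, dtype=bool)
    r0, c0 = corner
    filled = 0
    r = r0
    while filled < n_pix and r < mask.shape[0]:
        width = min(side, n_pix - filled, mask.shape[1] - c0)
        mask[r, c0:c0 + width] = True
        filled += width
        r += 1
    if filled < n_pix:
        raise ValueError("mediastinal box does not fit inside the image")
    return RoiSpec(mask=mask, label="mediastinum")
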