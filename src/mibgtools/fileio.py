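"""File I/O: NIfTI volumes and planar images, CSV profiles, YAML specs.

NIfTI (via nibabel) is the native interchange format for volumes and planar
scans; segment profiles, washout maps and truth tables travel as plain CSV;
phantom and cohort specifications as YAML.  Every writer has a matching
reader that round-trips values exactly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import CohortSpec, PhantomSpec
from .planar import PlanarScan, RoiSpec
from .polar import LvAxis, LvVolume, SegmentProfile, WashoutMap

__all__ = [
    "save_volume", "load_volume",
    "save_planar", "load_planar",
    "save_roi", "load_roi",
    "save_profile", "load_profile",
    "save_washout", "load_washout",
    "save_phantom_spec", "load_phantom_spec",
    "save_cohort_spec", "load_cohort_spec",
    "save_truth_table",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_volume(volume: LvVolume, path) -> None:
    img = nib.Nifti1Image(volume.counts.astype(np.float64), _affine(volume.voxel_size_mm))
    hdr = {
        "timepoint": volume.timepoint,
        "axis": {
            "base": list(volume.axis.base),
            "apex": list(volume.axis.apex),
            "angular_reference": list(volume.axis.angular_reference),
        },
    }
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension("comment", yaml.safe_dump(hdr).encode())
    )
    nib.save(img, str(path))


def load_volume(path) -> LvVolume:
    img = nib.load(str(path))
    meta = None
    for ext in img.header.extensions:
        try:
            meta = yaml.safe_load(ext.get_content().decode())
        except Exception:
            continue
        if isinstance(meta, dict) and "axis" in meta:
            break
    if meta is None or "axis" not in meta:
        raise ValueError(f"{path}: no LV axis metadata found in NIfTI extensions")
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    axis = LvAxis(
        base=tuple(meta["axis"]["base"]),
        apex=tuple(meta["axis"]["apex"]),
        angular_reference=tuple(meta["axis"]["angular_reference"]),
    )
    return LvVolume(
        counts=np.asanyarray(img.dataobj, dtype=float),
        voxel_size_mm=vs,
        axis=axis,
        timepoint=meta.get("timepoint", "late_4h"),
    )


def save_planar(scan: PlanarScan, path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(scan.counts).to_csv(path, index=False, header=False)
        return
    img = nib.Nifti1Image(
        scan.counts.astype(np.float64), _affine(list(scan.pixel_size_mm) + [1.0])
    )
    meta = {"timepoint": scan.timepoint, "acquisition_offset_h": scan.acquisition_offset_h}
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension("comment", yaml.safe_dump(meta).encode())
    )
    nib.save(img, str(path))


def load_planar(path, timepoint: str | None = None) -> PlanarScan:
    path = Path(path)
    if path.suffix == ".csv":
        counts = pd.read_csv(path, header=None).to_numpy(dtype=float)
        if timepoint is None:
            raise ValueError("timepoint must be given when loading a CSV planar image")
        return PlanarScan(counts=counts, pixel_size_mm=(1.0, 1.0), timepoint=timepoint)
    img = nib.load(str(path))
    meta = {}
    for ext in img.header.extensions:
        try:
            cand = yaml.safe_load(ext.get_content().decode())
        except Exception:
            continue
        if isinstance(cand, dict) and "timepoint" in cand:
            meta = cand
            break
    counts = np.asanyarray(img.dataobj, dtype=float)
    vs = tuple(float(v) for v in img.header.get_zooms()[:2])
    return PlanarScan(
        counts=counts,
        pixel_size_mm=vs,
        timepoint=timepoint or meta.get("timepoint", "late_4h"),
        acquisition_offset_h=meta.get("acquisition_offset_h"),
    )


def save_roi(roi: RoiSpec, path) -> None:
    """Run-length CSV: one row per (row, col_start, col_stop) run."""
    runs = []
    for r, row in enumerate(roi.mask):
        padded = np.diff(np.concatenate([[0], row.astype(int), [0]]))
        starts = np.nonzero(padded == 1)[0]
        stops = np.nonzero(padded == -1)[0]
        runs += [(r, int(a), int(b)) for a, b in zip(starts, stops)]
    df = pd.DataFrame(runs, columns=["row", "col_start", "col_stop"])
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# label={roi.label} shape={roi.mask.shape[0]}x{roi.mask.shape[1]}\n")
        df.to_csv(fh, index=False)


def load_roi(path) -> RoiSpec:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh)
    rows, cols = (int(x) for x in meta["shape"].split("x"))
    mask = np.zeros((rows, cols), dtype=bool)
    for _, run in df.iterrows():
        mask[int(run.row), int(run.col_start):int(run.col_stop)] = True
    return RoiSpec(mask=mask, label=meta["label"])


def save_profile(profile: SegmentProfile, path) -> None:
    pd.DataFrame(
        {"segment_id": np.arange(1, 18), "uptake_pct": profile.values}
    ).to_csv(path, index=False)


def load_profile(path, timepoint: str = "late_4h") -> SegmentProfile:
    df = pd.read_csv(path)
    df = df.sort_values("segment_id")
    return SegmentProfile(values=df["uptake_pct"].to_numpy(dtype=float), timepoint=timepoint)


def save_washout(wmap: WashoutMap, path) -> None:
    pd.DataFrame(
        {"segment_id": np.arange(1, 18), "washout_pp": wmap.values}
    ).to_csv(path, index=False)


def load_washout(path) -> WashoutMap:
    df = pd.read_csv(path).sort_values("segment_id")
    return WashoutMap(values=df["washout_pp"].to_numpy(dtype=float))


def save_truth_table(study, path) -> None:
    """Truth CSV: segment_id, uptake_early, uptake_late, washout."""
    pd.DataFrame(
        {
            "segment_id": np.arange(1, 18),
            "uptake_early": study.truth_uptake_early.values,
            "uptake_late": study.truth_uptake_late.values,
            "washout": study.truth_washout.values,
        }
    ).to_csv(path, index=False)


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_dict(spec), fh, sort_keys=False)


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("grid_shape", "voxel_size_mm", "lv_center", "lv_radii_mm",
                "segment_activity_early", "segment_activity_late"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomSpec(**raw)


def save_cohort_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_dict(spec), fh, sort_keys=False)


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        return CohortSpec(**yaml.safe_load(fh))


def _plain(v):
    if isinstance(v, (tuple, list)):
        return [_plain(x) for x in v]
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


def _spec_dict(spec) -> dict:
    return {k: _plain(v) for k, v in asdict(spec).items()}
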