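"""Readers and writers for the pipeline's standard formats.

NIfTI-1 (via nibabel) for dynamic images, parametric maps and masks;
SIF-style plain text for frame timing; TSV for single time-activity
curves; CSV for longitudinal tables; JSON for summaries and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DataError, ScheduleError
from .frames import FrameSchedule, read_sif, write_sif
from .image import DynamicImage, ParametricMaps
from .kinetics import TimeActivityCurve
from .longitudinal import validate_longitudinal

__all__ = [
    "read_dynamic_image",
    "write_dynamic_image",
    "read_tac_tsv",
    "write_tac_tsv",
    "read_longitudinal_csv",
    "write_longitudinal_csv",
    "write_maps",
    "read_map",
    "write_json_report",
]

TAC_COLUMNS = ("frame_start_s", "frame_duration_s", "activity_kBq_per_mL")


def _affine(voxel_size_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    aff[:3, 3] = origin_mm
    return aff


def write_dynamic_image(image: DynamicImage, nifti_path, sif_path=None) -> None:
    nii = nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size_mm, image.origin_mm))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(nifti_path))
    if sif_path is not None:
        write_sif(image.schedule, sif_path)


def read_dynamic_image(nifti_path, timing_path) -> DynamicImage:
    """Load a 4-D NIfTI and attach its SIF frame schedule.

    The voxel size and origin are taken from the affine's scaling and
    translation (images are assumed resampled to template space, axes
    aligned).  Frame-count disagreement between image and timing file is
    an error.
    """
    nii = nib.load(str(nifti_path))
    data = np.asanyarray(nii.dataobj).astype(float)
    if data.ndim != 4:
        raise DataError(f"{nifti_path}: expected a 4-D dynamic image, got {data.ndim}-D")
    schedule = read_sif(timing_path)
    if data.shape[3] != schedule.n_frames:
        raise ScheduleError(
            f"{nifti_path} has {data.shape[3]} frames but {timing_path} lists {schedule.n_frames}"
        )
    aff = nii.affine
    voxel_size = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    return DynamicImage(data, voxel_size, schedule, origin)


def write_tac_tsv(tac: TimeActivityCurve, path) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.frame_start_s,
            "frame_duration_s": tac.schedule.frame_duration_s,
            "activity_kBq_per_mL": tac.activity,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tac_tsv(path) -> TimeActivityCurve:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing TAC columns {missing}")
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(float), df["frame_duration_s"].to_numpy(float)
    )
    return TimeActivityCurve(schedule, df["activity_kBq_per_mL"].to_numpy(float))


def write_longitudinal_csv(table: pd.DataFrame, path) -> None:
    validate_longitudinal(table)
    table.to_csv(path, index=False)


def read_longitudinal_csv(path) -> pd.DataFrame:
    return validate_longitudinal(pd.read_csv(path))


def write_maps(maps: ParametricMaps, out_dir, prefix: str = "srtm") -> dict:
    """Write BP/R1/k2 volumes, the validity mask and provenance JSON.

    Returns a dict of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(maps.voxel_size_mm, np.zeros(3))
    paths = {}
    for name, vol in (
        ("bp", maps.bp_map),
        ("r1", maps.r1_map),
        ("k2", maps.k2_map),
    ):
        p = out_dir / f"{prefix}_{name}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(p))
        paths[name] = p
    p = out_dir / f"{prefix}_valid_mask.nii"
    nib.save(nib.Nifti1Image(maps.valid_mask.astype(np.uint8), aff), str(p))
    paths["valid_mask"] = p
    p = out_dir / f"{prefix}_provenance.json"
    write_json_report(maps.provenance, p)
    paths["provenance"] = p
    return paths


def read_map(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(float)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_json_report(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
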