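"""Dynamic images, spherical VOIs and voxelwise BP_ND parametric mapping.

Coordinate convention: voxel-centre based, 0-indexed; the centre of voxel
(i, j, k) sits at ``origin + index * voxel_size`` millimetres in template
space.  Registration to that space is assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import EmptyRegionError, ScheduleError
from .frames import FrameSchedule
from .kinetics import (
    ThetaGrid,
    TimeActivityCurve,
    _resolve_weights,
    bfm_solve_many,
    build_basis,
)

__all__ = ["DynamicImage", "SphericalVOI", "ParametricMaps", "extract_voi_tac", "fit_image"]


@dataclass
class DynamicImage:
    """4-D activity volume (x, y, z, frame) in kBq/mL on a frame schedule."""

    data: np.ndarray
    voxel_size_mm: np.ndarray
    schedule: FrameSchedule
    origin_mm: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ScheduleError(f"dynamic image must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ScheduleError(
                f"image has {self.data.shape[3]} frames but schedule has {self.schedule.n_frames}"
            )
        self.voxel_size_mm = np.broadcast_to(
            np.asarray(self.voxel_size_mm, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size_mm <= 0):
            raise ScheduleError("voxel sizes must be positive")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def spatial_shape(self):
        return self.data.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def coordinate_grids(self):
        """Voxel-centre mm coordinates, three broadcastable axis arrays."""
        nx, ny, nz = self.spatial_shape
        ax = [
            self.origin_mm[d] + np.arange(n) * self.voxel_size_mm[d]
            for d, n in zip(range(3), (nx, ny, nz))
        ]
        return ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]

    def voxel_tac(self, index) -> TimeActivityCurve:
        i, j, k = index
        return TimeActivityCurve(self.schedule, self.data[i, j, k, :])


@dataclass(frozen=True)
class SphericalVOI:
    """Uniform spherical volume of interest defined by centre (mm) and volume (cm^3).

    The radius is derived, r = (3V / 4 pi)^(1/3); membership is voxel
    centres strictly inside the sphere.  A 0.014 cm^3 reference VOI on the
    contralateral hemisphere is the conventional SRTM input for a focal
    unilateral lesion.
    """

    centre_mm: np.ndarray
    volume_cm3: float

    def __post_init__(self):
        object.__setattr__(self, "centre_mm", np.asarray(self.centre_mm, dtype=float))
        if self.centre_mm.shape != (3,):
            raise EmptyRegionError("VOI centre must be a 3-vector (mm)")
        if self.volume_cm3 <= 0:
            raise EmptyRegionError("VOI volume must be positive")

    @property
    def radius_mm(self) -> float:
        volume_mm3 = self.volume_cm3 * 1000.0
        return float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))

    @classmethod
    def from_radius(cls, centre_mm, radius_mm: float) -> "SphericalVOI":
        volume_cm3 = (4.0 / 3.0) * np.pi * radius_mm**3 / 1000.0
        return cls(np.asarray(centre_mm, dtype=float), volume_cm3)

    def membership(self, image: DynamicImage) -> np.ndarray:
        gx, gy, gz = image.coordinate_grids()
        d2 = (
            (gx - self.centre_mm[0]) ** 2
            + (gy - self.centre_mm[1]) ** 2
            + (gz - self.centre_mm[2]) ** 2
        )
        return d2 < self.radius_mm**2


@dataclass
class ParametricMaps:
    """Voxelwise SRTM parameter volumes with a validity mask and provenance.

    Parameter values are defined (finite) only where ``valid_mask`` is
    true; failed voxels are NaN, never interpolated.
    """

    bp_map: np.ndarray
    r1_map: np.ndarray
    k2_map: np.ndarray
    valid_mask: np.ndarray
    voxel_size_mm: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def extract_voi_tac(image: DynamicImage, voi: SphericalVOI) -> TimeActivityCurve:
    """Unweighted per-frame mean activity over the sphere's member voxels."""
    member = voi.membership(image)
    n = int(member.sum())
    if n == 0:
        raise EmptyRegionError(
            f"VOI at {voi.centre_mm} (r={voi.radius_mm:.3f} mm) contains no voxel centres"
        )
    tac = image.data[member].mean(axis=0)
    return TimeActivityCurve(image.schedule, tac)


def fit_image(
    image: DynamicImage,
    ref: TimeActivityCurve,
    grid: ThetaGrid = ThetaGrid(),
    weights="uniform",
    mask: Optional[np.ndarray] = None,
) -> ParametricMaps:
    """Voxelwise basis-function SRTM fit of a dynamic image.

    Basis curves are computed once and shared across voxels; the per-voxel
    work is only the two-parameter linear stage.  Voxels whose fit is
    degenerate (zero signal, singular design) are excluded from
    ``valid_mask`` rather than raising.
    """
    if not image.schedule.same_grid(ref.schedule):
        raise ScheduleError("image and reference are on different frame schedules")
    w = _resolve_weights(weights, image.schedule)
    basis = build_basis(ref, grid)
    thetas = grid.values

    shape = image.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ScheduleError("mask shape does not match image spatial shape")

    Y = image.data[mask].T  # (n_frames, n_voxels)
    bp = np.full(shape, np.nan)
    r1 = np.full(shape, np.nan)
    k2 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    if Y.shape[1] > 0 and np.any(ref.activity != 0):
        b1, b2, idx, rss, ok = bfm_solve_many(Y, ref.activity, basis, w)
        theta = thetas[idx]
        k2_v = b2 + b1 * theta
        bp_v = np.where(ok, k2_v / theta - 1.0, np.nan)
        bp[mask] = np.where(ok, bp_v, np.nan)
        r1[mask] = np.where(ok, b1, np.nan)
        k2[mask] = np.where(ok, k2_v, np.nan)
        valid[mask] = ok
    provenance = {
        "grid": grid.to_dict(),
        "weights": weights if isinstance(weights, str) else "custom",
        "n_voxels_attempted": int(mask.sum()),
        "n_voxels_failed": int(mask.sum() - valid.sum()),
    }
    return ParametricMaps(
        bp_map=bp,
        r1_map=r1,
        k2_map=k2,
        valid_mask=valid,
        voxel_size_mm=image.voxel_size_mm.copy(),
        provenance=provenance,
    )
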