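"""Iso-contour lesion extraction from BP_ND parametric maps.

A focal lesion is delineated as the connected set of voxels whose BP_ND
exceeds a threshold tied to the regional peak.  The threshold is a
reproducible rule — a fraction of the peak value (default 0.5) or an
absolute BP_ND — recorded in the segment, replacing interactive threshold
picking; connectivity is 26-neighbour by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import EmptyRegionError, EmptySegmentationError
from .image import ParametricMaps

__all__ = ["LesionSegment", "LesionSummary", "isocontour_segment", "summarize_lesion"]


@dataclass
class LesionSegment:
    """Iso-contour segmentation result: mask, threshold used, peak voxel."""

    mask: np.ndarray
    threshold_value: float
    peak_index: Tuple[int, int, int]
    connected: bool = True

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LesionSummary:
    """Regional summary over a lesion mask."""

    mean_bp: float
    volume_mm3: float
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "mean_bp": self.mean_bp,
            "volume_mm3": self.volume_mm3,
            "n_voxels": self.n_voxels,
        }


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def isocontour_segment(
    maps: ParametricMaps,
    search_region: Optional[np.ndarray] = None,
    fraction: Optional[float] = 0.5,
    absolute: Optional[float] = None,
    connectivity: int = 26,
) -> LesionSegment:
    """Segment the lesion as the iso-contour component around the regional peak.

    The peak is the maximum valid BP_ND voxel inside ``search_region``
    (whole valid map when omitted).  Threshold is ``absolute`` if given,
    otherwise ``fraction`` times the peak value; the mask is the set of
    valid voxels with BP_ND >= threshold restricted to the connected
    component containing the peak.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    bp = maps.bp_map
    region = maps.valid_mask.copy()
    if search_region is not None:
        region &= np.asarray(search_region, dtype=bool)
    if not region.any():
        raise EmptyRegionError("search region contains no valid voxels")
    bp_region = np.where(region, bp, -np.inf)
    peak_index = np.unravel_index(np.nanargmax(bp_region), bp.shape)
    peak_value = bp[peak_index]
    threshold = float(absolute) if absolute is not None else float(fraction) * float(peak_value)
    candidate = maps.valid_mask & (np.nan_to_num(bp, nan=-np.inf) >= threshold)
    if not candidate[peak_index]:
        raise EmptySegmentationError(
            f"no voxel reaches threshold {threshold:.4g} (peak {peak_value:.4g})"
        )
    labels, _ = ndimage.label(candidate, structure=_STRUCTURES[connectivity])
    mask = labels == labels[peak_index]
    return LesionSegment(
        mask=mask,
        threshold_value=threshold,
        peak_index=tuple(int(i) for i in peak_index),
        connected=True,
    )


def summarize_lesion(maps: ParametricMaps, segment: LesionSegment) -> LesionSummary:
    """Mean BP_ND and physical volume over a lesion segment."""
    mask = segment.mask
    if not mask.any():
        raise EmptyRegionError("empty lesion mask")
    if np.any(mask & ~maps.valid_mask):
        raise EmptyRegionError("lesion mask includes invalid (unfitted) voxels")
    n = int(mask.sum())
    return LesionSummary(
        mean_bp=float(maps.bp_map[mask].mean()),
        volume_mm3=n * maps.voxel_volume_mm3,
        n_voxels=n,
    )
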