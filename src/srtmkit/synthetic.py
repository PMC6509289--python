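"""Synthetic dynamic-PET study generator.

Everything the pipeline consumes can be generated here with no external
data: a biexponential contralateral reference curve, SRTM-consistent
voxel kinetics, a lesion-bearing 4-D rat-brain-scale phantom on a
45-minute 50-frame schedule, count-statistics-inspired Gaussian frame
noise, and longitudinal study tables from a compound-symmetry model with
an injectable cessation-rebound effect.  All generators are pure
functions of (spec, seed).

The default phantom is 60 x 60 x 40 voxels at 0.5 mm isotropic with three
kinetic classes sharing R1 = 1 and k2 = 0.3 /min: low-binding background
(BP_ND = 0.1), a focal striatum-analogue lesion sphere (BP_ND = 1.5), and
a contralateral reference patch with BP_ND = 0 at the lesion's mirror
position, inside which the reference VOI is placed.  All apparent efflux
rates k2a then lie inside the default basis grid [0.05, 0.4] /min, so
every voxel is identifiable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ScheduleError
from .frames import FrameSchedule, make_frame_schedule
from .image import DynamicImage, SphericalVOI
from .kinetics import SRTMParameters, TimeActivityCurve, forward_srtm

__all__ = [
    "DEFAULT_FRAMING",
    "ReferenceCurveSpec",
    "NoiseModel",
    "PhantomSpec",
    "Phantom",
    "default_schedule",
    "make_reference_tac",
    "add_noise",
    "build_phantom",
    "rebound_cell_means",
    "make_longitudinal_dataset",
    "sigma0_for_peak_fraction",
]

# 30 x 10 s early frames, 15 x 60 s, 5 x 300 s late frames: 50 frames, 45 min
DEFAULT_FRAMING: Tuple[Tuple[int, float], ...] = ((30, 10), (15, 60), (5, 300))

STUDY_DAYS: Tuple[int, ...] = (30, 44, 65, 86, 142)
STUDY_GROUPS: Tuple[str, str] = ("treated", "control")


def default_schedule() -> FrameSchedule:
    return make_frame_schedule(DEFAULT_FRAMING)


@dataclass(frozen=True)
class ReferenceCurveSpec:
    """Biexponential reference curve C_R(t) = A (e^{-l_slow t} - e^{-l_fast t}).

    Zero at t = 0, a tracer-delivery peak at ln(l_fast/l_slow) /
    (l_fast - l_slow) minutes, then slow washout — the qualitative shape
    of a low-binding tissue curve after a bolus injection.
    """

    amplitude: float = 100.0  # kBq/mL
    lambda_fast: float = 0.6  # 1/min
    lambda_slow: float = 0.03  # 1/min

    def __post_init__(self):
        if not (self.lambda_fast > self.lambda_slow > 0):
            raise ParameterError("require lambda_fast > lambda_slow > 0")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")

    @property
    def peak_time_min(self) -> float:
        return float(
            np.log(self.lambda_fast / self.lambda_slow)
            / (self.lambda_fast - self.lambda_slow)
        )


def make_reference_tac(
    spec: ReferenceCurveSpec, schedule: Optional[FrameSchedule] = None
) -> TimeActivityCurve:
    """Frame-midpoint samples of the biexponential, with the exact analytic tail attached."""
    if schedule is None:
        schedule = default_schedule()
    return TimeActivityCurve.from_exponentials(
        schedule,
        coeffs=[spec.amplitude, -spec.amplitude],
        rates=[spec.lambda_slow, spec.lambda_fast],
    )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian frame noise with SD sigma0 * sqrt(C / dt_min).

    The variance scales with activity and inversely with frame duration,
    mimicking count statistics in reconstructed frames; noise is
    independent across frames and voxels.  sigma0 = 0 reproduces the
    noiseless signal exactly.
    """

    sigma0: float = 0.0

    def __post_init__(self):
        if self.sigma0 < 0:
            raise ParameterError("sigma0 must be non-negative")

    def frame_sd(self, values: np.ndarray, duration_min: np.ndarray) -> np.ndarray:
        return self.sigma0 * np.sqrt(np.maximum(values, 0.0) / duration_min)


def add_noise(obj, model: NoiseModel, seed: int):
    """Seeded noisy copy of a curve or dynamic image (sigma0=0: exact copy)."""
    rng = np.random.default_rng(seed)
    if isinstance(obj, TimeActivityCurve):
        if model.sigma0 == 0:
            return TimeActivityCurve(obj.schedule, obj.activity.copy(), obj.units, obj.analytic)
        sd = model.frame_sd(obj.activity, obj.schedule.duration_min)
        noisy = obj.activity + rng.standard_normal(obj.activity.shape) * sd
        return TimeActivityCurve(obj.schedule, noisy, obj.units, analytic=None)
    if isinstance(obj, DynamicImage):
        if model.sigma0 == 0:
            return DynamicImage(
                obj.data.copy(), obj.voxel_size_mm.copy(), obj.schedule, obj.origin_mm.copy()
            )
        sd = model.frame_sd(obj.data, obj.schedule.duration_min[None, None, None, :])
        noisy = obj.data + rng.standard_normal(obj.data.shape) * sd
        return DynamicImage(noisy, obj.voxel_size_mm.copy(), obj.schedule, obj.origin_mm.copy())
    raise TypeError(f"cannot add noise to {type(obj).__name__}")


def sigma0_for_peak_fraction(curve: TimeActivityCurve, fraction: float) -> float:
    """sigma0 such that the peak-activity frame has SD = fraction * peak value.

    Inverts the noise law sigma = sigma0 * sqrt(C / dt) at the frame where
    the curve peaks; a handy way to specify noise as "x% at the peak".
    """
    i = int(np.argmax(curve.activity))
    c_peak = float(curve.activity[i])
    if c_peak <= 0:
        raise ParameterError("curve peak must be positive to calibrate noise")
    dt = float(curve.schedule.duration_min[i])
    return fraction * np.sqrt(c_peak * dt)


def _default_background() -> SRTMParameters:
    return SRTMParameters.from_bp(r1=1.0, k2=0.3, bp_nd=0.1)


def _default_lesion() -> SRTMParameters:
    return SRTMParameters.from_bp(r1=1.0, k2=0.3, bp_nd=1.5)


def _default_reference() -> SRTMParameters:
    return SRTMParameters.from_bp(r1=1.0, k2=0.3, bp_nd=0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of a lesion-bearing dynamic phantom.

    The lesion sphere sits left of the sagittal midline; the reference
    patch (binding-free tissue hosting the reference VOI) sits at the
    lesion's mirror position on the contralateral side.
    """

    shape: Tuple[int, int, int] = (60, 60, 40)
    voxel_size_mm: float = 0.5
    background: SRTMParameters = field(default_factory=_default_background)
    lesion_centre_mm: Tuple[float, float, float] = (9.0, 15.0, 10.0)
    lesion_radius_mm: float = 2.0
    lesion: SRTMParameters = field(default_factory=_default_lesion)
    reference_centre_mm: Optional[Tuple[float, float, float]] = None
    reference_radius_mm: float = 2.5
    reference: SRTMParameters = field(default_factory=_default_reference)
    ref_curve: ReferenceCurveSpec = field(default_factory=ReferenceCurveSpec)
    noise_sigma0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        extent = (np.asarray(self.shape) - 1) * self.voxel_size_mm
        centre = np.asarray(self.lesion_centre_mm)
        if np.any(centre - self.lesion_radius_mm < 0) or np.any(
            centre + self.lesion_radius_mm > extent
        ):
            raise ParameterError("lesion sphere must lie inside the grid")
        if self.lesion.bp_nd < self.background.bp_nd:
            raise ParameterError("lesion BP_ND must not be below background BP_ND")

    @property
    def mirror_reference_centre_mm(self) -> np.ndarray:
        """Reference patch centre: lesion mirrored across the x midline."""
        if self.reference_centre_mm is not None:
            return np.asarray(self.reference_centre_mm, dtype=float)
        extent_x = (self.shape[0] - 1) * self.voxel_size_mm
        c = np.asarray(self.lesion_centre_mm, dtype=float).copy()
        c[0] = extent_x - c[0]
        return c


@dataclass
class Phantom:
    """A generated phantom plus its ground truth."""

    image: DynamicImage
    truth_bp: np.ndarray
    truth_r1: np.ndarray
    truth_k2: np.ndarray
    lesion_mask: np.ndarray
    reference_mask: np.ndarray
    reference_voi: SphericalVOI
    reference_tac: TimeActivityCurve
    spec: PhantomSpec


def _sphere_mask(image: DynamicImage, centre_mm, radius_mm) -> np.ndarray:
    return SphericalVOI.from_radius(centre_mm, radius_mm).membership(image)


def build_phantom(
    spec: PhantomSpec = PhantomSpec(),
    schedule: Optional[FrameSchedule] = None,
    reference_voi_volume_cm3: float = 0.014,
) -> Phantom:
    """Simulate the dynamic image and return it with exact truth maps.

    Every voxel's curve is the SRTM forward model of its class parameters
    driven by the shared reference curve, plus optional frame noise; the
    truth maps encode the generating parameters voxel by voxel.  The
    returned reference VOI (default 0.014 cm^3) is centred in the
    binding-free contralateral patch.
    """
    if schedule is None:
        schedule = default_schedule()
    ref_tac = make_reference_tac(spec.ref_curve, schedule)
    vox = spec.voxel_size_mm
    n_frames = schedule.n_frames
    data = np.empty(spec.shape + (n_frames,))
    image = DynamicImage(data, np.full(3, vox), schedule)

    ref_centre = spec.mirror_reference_centre_mm
    lesion_mask = _sphere_mask(image, spec.lesion_centre_mm, spec.lesion_radius_mm)
    reference_mask = _sphere_mask(image, ref_centre, spec.reference_radius_mm)
    if not reference_mask.any():
        raise ParameterError("reference patch contains no voxels")

    regions = (
        (None, spec.background),
        (reference_mask, spec.reference),
        (lesion_mask, spec.lesion),
    )
    truth_bp = np.empty(spec.shape)
    truth_r1 = np.empty(spec.shape)
    truth_k2 = np.empty(spec.shape)
    for mask, params in regions:
        curve = forward_srtm(params, ref_tac).activity
        if mask is None:
            data[...] = curve
            truth_bp[...] = params.bp_nd
            truth_r1[...] = params.r1
            truth_k2[...] = params.k2
        else:
            data[mask] = curve
            truth_bp[mask] = params.bp_nd
            truth_r1[mask] = params.r1
            truth_k2[mask] = params.k2

    if spec.noise_sigma0 > 0:
        image = add_noise(image, NoiseModel(spec.noise_sigma0), spec.seed)

    voi = SphericalVOI(ref_centre, reference_voi_volume_cm3)
    return Phantom(
        image=image,
        truth_bp=truth_bp,
        truth_r1=truth_r1,
        truth_k2=truth_k2,
        lesion_mask=lesion_mask,
        reference_mask=reference_mask,
        reference_voi=voi,
        reference_tac=ref_tac,
        spec=spec,
    )


def rebound_cell_means(
    baseline: float = 1.5,
    rebound_amplitude: float = 0.55,
    groups: Tuple[str, str] = STUDY_GROUPS,
    days: Sequence[int] = STUDY_DAYS,
) -> Dict[Tuple[str, int], float]:
    """Cell-mean pattern mimicking a treatment-cessation rebound.

    Both groups start at the same baseline; the control group declines
    slowly as the lesion ages.  The treated group dips slightly under
    treatment, overshoots the control trajectory at the third time point
    (shortly after treatment stops) by ``rebound_amplitude``, then
    returns to the control level by the last day.
    """
    treated, control = groups
    d = list(days)
    control_traj = {d[0]: baseline, d[1]: baseline - 0.05, d[2]: baseline - 0.15,
                    d[3]: baseline - 0.3, d[4]: baseline - 0.4}
    treated_traj = {d[0]: baseline, d[1]: baseline - 0.25,
                    d[2]: control_traj[d[2]] + rebound_amplitude,
                    d[3]: baseline - 0.2, d[4]: control_traj[d[4]]}
    out = {}
    for day in d:
        out[(treated, day)] = treated_traj[day]
        out[(control, day)] = control_traj[day]
    return out


def make_longitudinal_dataset(
    cell_means: Dict[Tuple[str, object], float],
    n_per_group: int = 4,
    sigma_animal: float = 0.2,
    sigma_resid: float = 0.2,
    seed: int = 0,
    measure: Optional[str] = None,
) -> pd.DataFrame:
    """Draw a longitudinal table from the compound-symmetry model.

    value = cell mean + animal intercept (SD ``sigma_animal``) + residual
    (SD ``sigma_resid``).  Zero variances reproduce the cell-mean pattern
    exactly.  Columns: animal_id, group, day, value (+ measure if given).
    """
    if sigma_animal < 0 or sigma_resid < 0:
        raise ParameterError("variance components must be non-negative")
    groups = sorted({g for g, _ in cell_means})
    days = sorted({d for g, d in cell_means if g == groups[0]})
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        for i in range(n_per_group):
            animal = f"{group}_{i + 1:02d}"
            intercept = rng.normal(0.0, sigma_animal) if sigma_animal > 0 else 0.0
            for day in days:
                resid = rng.normal(0.0, sigma_resid) if sigma_resid > 0 else 0.0
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "day": day,
                        "value": cell_means[(group, day)] + intercept + resid,
                    }
                )
    table = pd.DataFrame(rows)
    if measure is not None:
        table.insert(3, "measure", measure)
    return table
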