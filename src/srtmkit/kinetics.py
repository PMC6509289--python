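"""Simplified reference tissue model (SRTM): forward simulation and fitting.

The SRTM describes a target-tissue time-activity curve C_T(t) from a
reference-region curve C_R(t) assumed free of specific binding::

    C_T(t) = R1 * C_R(t) + (k2 - R1*k2a) * [C_R (x) exp(-k2a*t)]

with R1 the relative delivery (K1/K1'), k2 the target efflux rate (1/min)
and k2a the apparent efflux rate (1/min).  The endpoint is the
non-displaceable binding potential

    BP_ND = k2 / k2a - 1 .

The basis-function method (BFM) fits this model by discretising k2a (often
written theta) on a grid, precomputing the basis curve
B_theta = C_R (x) exp(-theta*t) for each grid value, solving the
two-parameter weighted linear least-squares problem
C_T ~ beta1*C_R + beta2*B_theta per grid value, and keeping the
minimum-RSS solution.  Because the basis curves do not depend on the
target, a whole image can be fitted with one basis construction and a
cheap linear stage per voxel.

Continuous-time reconstruction of C_R: curves that carry an exact
sum-of-exponentials description (synthetic references do) are convolved in
closed form; sampled curves are reconstructed by piecewise-linear
interpolation through (frame midpoint, value) with C_R(0)=0 and convolved
analytically segment by segment, which is exact for the interpolant.
The model is evaluated at frame midpoints.  Rate constants are per minute;
schedules are stored in seconds and converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    ConvergenceError,
    InsufficientDataError,
    ParameterError,
    ScheduleError,
    SingularFitError,
)
from .frames import FrameSchedule

__all__ = [
    "ExponentialCurve",
    "TimeActivityCurve",
    "ThetaGrid",
    "SRTMParameters",
    "SRTMFitResult",
    "exp_convolve",
    "forward_srtm",
    "build_basis",
    "fit_srtm_bfm",
    "fit_srtm_nls",
]

_RATE_TOL = 1e-10  # below this |theta - rate| the degenerate t*exp(-theta t) limit is used


@dataclass(frozen=True)
class ExponentialCurve:
    """Exact analytic curve C(t) = sum_i coeffs[i] * exp(-rates[i] * t), t in minutes."""

    coeffs: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        r = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if c.shape != r.shape:
            raise ParameterError("coeffs and rates must have equal length")
        if np.any(r < 0):
            raise ParameterError("exponential rates must be non-negative")
        object.__setattr__(self, "coeffs", c)
        object.__setattr__(self, "rates", r)

    def value(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return np.einsum("i,i...->...", self.coeffs, np.exp(-np.multiply.outer(self.rates, t)))

    def convolve_exp(self, thetas: np.ndarray, t_min: np.ndarray) -> np.ndarray:
        """Closed-form int_0^t C(s) exp(-theta (t-s)) ds, shape (n_theta, n_t)."""
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        t = np.asarray(t_min, dtype=float)
        out = np.zeros((thetas.size, t.size))
        et_theta = np.exp(-np.multiply.outer(thetas, t))  # (n_theta, n_t)
        for c, r in zip(self.coeffs, self.rates):
            er = np.exp(-r * t)  # (n_t,)
            diff = thetas - r
            near = np.abs(diff) < _RATE_TOL
            safe = np.where(near, 1.0, diff)
            term = (er[None, :] - et_theta) / safe[:, None]
            if np.any(near):
                # limit theta -> r: t * exp(-r t)
                term[near] = t * er
            out += c * term
        return out


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration for one region or voxel.

    ``analytic`` optionally records the exact continuous-time curve the
    samples were drawn from (synthetic references); convolution then uses
    the closed form instead of the piecewise-linear reconstruction.
    """

    schedule: FrameSchedule
    activity: np.ndarray
    units: str = "kBq/mL"
    analytic: Optional[ExponentialCurve] = None

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise ScheduleError(
                f"activity has {act.size} values for {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(act)):
            raise ScheduleError("activity values must be finite")

    @classmethod
    def from_exponentials(cls, schedule: FrameSchedule, coeffs, rates, units="kBq/mL"):
        model = ExponentialCurve(np.asarray(coeffs), np.asarray(rates))
        return cls(schedule, model.value(schedule.mid_min), units=units, analytic=model)

    def scaled(self, factor: float) -> "TimeActivityCurve":
        analytic = None
        if self.analytic is not None:
            analytic = ExponentialCurve(self.analytic.coeffs * factor, self.analytic.rates)
        return TimeActivityCurve(self.schedule, self.activity * factor, self.units, analytic)


@dataclass(frozen=True)
class ThetaGrid:
    """Discretisation of the apparent efflux rate k2a (theta) for the BFM.

    Default spacing is logarithmic, the classical choice for exponential
    rate grids; linear spacing is available.
    """

    theta_min: float = 0.05
    theta_max: float = 0.4
    n_bases: int = 100
    spacing: str = "log"

    def __post_init__(self):
        if not (0 < self.theta_min < self.theta_max):
            raise ParameterError("require 0 < theta_min < theta_max")
        if self.n_bases < 2:
            raise ParameterError("need at least 2 basis functions")
        if self.spacing not in ("log", "linear"):
            raise ParameterError(f"unknown spacing {self.spacing!r}")

    @property
    def values(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.theta_min, self.theta_max, self.n_bases)
        return np.linspace(self.theta_min, self.theta_max, self.n_bases)

    def to_dict(self) -> dict:
        return {
            "theta_min": self.theta_min,
            "theta_max": self.theta_max,
            "n_bases": self.n_bases,
            "spacing": self.spacing,
        }


@dataclass(frozen=True)
class SRTMParameters:
    """SRTM parameter triple; BP_ND = k2/k2a - 1 is derived, never stored."""

    r1: float
    k2: float
    k2a: float

    def __post_init__(self):
        if not np.isfinite([self.r1, self.k2, self.k2a]).all():
            raise ParameterError("SRTM parameters must be finite")
        if self.k2a <= 0:
            raise ParameterError(f"k2a must be positive, got {self.k2a}")

    @property
    def bp_nd(self) -> float:
        return self.k2 / self.k2a - 1.0

    @classmethod
    def from_bp(cls, r1: float, k2: float, bp_nd: float) -> "SRTMParameters":
        if bp_nd <= -1:
            raise ParameterError("BP_ND must exceed -1 (k2a > 0)")
        return cls(r1=r1, k2=k2, k2a=k2 / (1.0 + bp_nd))


@dataclass
class SRTMFitResult:
    """One fitted curve: parameters, linear-stage coefficients, diagnostics.

    ``rss_profile`` (BFM only) stores the weighted RSS at every grid theta;
    ``rss`` is its minimum and ``chosen_index`` the argmin.
    """

    params: SRTMParameters
    coefficients: Tuple[float, float]
    rss: float
    chosen_index: Optional[int] = None
    rss_profile: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def bp_nd(self) -> float:
        return self.params.bp_nd


def _resolve_weights(weights, schedule: FrameSchedule) -> np.ndarray:
    if isinstance(weights, str):
        if weights == "uniform":
            return np.ones(schedule.n_frames)
        if weights == "duration":
            return schedule.duration_min.copy()
        raise ParameterError(f"unknown weight mode {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,):
        raise ParameterError("weights must have one value per frame")
    if np.any(w < 0) or not np.any(w > 0):
        raise ParameterError("weights must be non-negative and not all zero")
    return w


def _convolve_sampled(mid_min: np.ndarray, values: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Convolution of the piecewise-linear interpolant with exp(-theta t).

    Knots are (0, 0) followed by (midpoint, value); each segment integral
    has a closed form, accumulated with the semigroup recursion
    F(t_k) = F(t_{k-1}) e^{-theta dt} + segment integral.
    Returns shape (n_theta, n_frames), evaluated at the midpoints.
    """
    t = np.concatenate([[0.0], mid_min])
    v = np.concatenate([[0.0], values])
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    pos = thetas > 0
    out = np.empty((thetas.size, mid_min.size))
    acc = np.zeros(thetas.size)
    for k in range(1, t.size):
        dt = t[k] - t[k - 1]
        a = v[k - 1]
        b = (v[k] - v[k - 1]) / dt
        om = -np.expm1(-thetas * dt)  # 1 - exp(-theta dt), stable for small theta*dt
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = a * om / thetas + b * (dt / thetas - om / thetas**2)
        seg[~pos] = a * dt + 0.5 * b * dt * dt  # theta == 0: running integral
        acc = acc * (1.0 - om) + seg
        out[:, k - 1] = acc
    return out


def exp_convolve(ref: TimeActivityCurve, theta: float) -> np.ndarray:
    """Basis curve: per-frame values of int_0^t C_R(s) exp(-theta (t-s)) ds.

    ``theta`` is in 1/min; the result is evaluated at the frame midpoints.
    theta = 0 yields the running integral of C_R.
    """
    if theta < 0:
        raise ParameterError(f"theta must be non-negative, got {theta}")
    if ref.schedule.n_frames < 2:
        raise ScheduleError("reference curve needs at least 2 frames")
    t = ref.schedule.mid_min
    if ref.analytic is not None:
        return ref.analytic.convolve_exp(np.array([theta]), t)[0]
    return _convolve_sampled(t, ref.activity, np.array([theta]))[0]


def forward_srtm(params: SRTMParameters, ref: TimeActivityCurve) -> TimeActivityCurve:
    """Simulate the target curve C_T for given SRTM parameters and reference.

    When the reference carries an analytic exponential description the
    result does too (the SRTM output of a sum of exponentials is again a
    sum of exponentials), so nested simulations stay exact.
    """
    w2 = params.k2 - params.r1 * params.k2a
    conv = exp_convolve(ref, params.k2a)
    ct = params.r1 * ref.activity + w2 * conv
    analytic = None
    if ref.analytic is not None:
        c, r = ref.analytic.coeffs, ref.analytic.rates
        if np.all(np.abs(params.k2a - r) > _RATE_TOL):
            new_c = params.r1 * c + w2 * c / (params.k2a - r)
            tail = -w2 * np.sum(c / (params.k2a - r))
            analytic = ExponentialCurve(
                np.concatenate([new_c, [tail]]), np.concatenate([r, [params.k2a]])
            )
    return TimeActivityCurve(ref.schedule, ct, units=ref.units, analytic=analytic)


def build_basis(ref: TimeActivityCurve, grid: ThetaGrid) -> np.ndarray:
    """All basis curves for a grid, shape (n_bases, n_frames), theta ascending."""
    if ref.schedule.n_frames < 2:
        raise ScheduleError("reference curve needs at least 2 frames")
    thetas = grid.values
    t = ref.schedule.mid_min
    if ref.analytic is not None:
        return ref.analytic.convolve_exp(thetas, t)
    return _convolve_sampled(t, ref.activity, thetas)


def _linear_stage(y_w_sums, cr, basis, w):
    """Per-theta weighted 2-parameter least squares, vectorised over voxels.

    Parameters are the precomputed weighted sums for the targets plus the
    shared reference/basis terms.  Yields, for each grid theta,
    (beta1, beta2, rss, ok) arrays over voxels.
    """
    Y, s1y, yy = y_w_sums
    wc = w * cr
    s11 = float(cr @ wc)
    eps = np.finfo(float).eps
    for bj in basis:
        wb = w * bj
        s22 = float(bj @ wb)
        s12 = float(cr @ wb)
        det = s11 * s22 - s12 * s12
        if s11 <= 0 or s22 <= 0 or det <= 100 * eps * s11 * s22:
            nan = np.full(s1y.shape, np.nan)
            yield nan, nan, np.full(s1y.shape, np.inf), np.zeros(s1y.shape, dtype=bool)
            continue
        s2y = wb @ Y
        b1 = (s22 * s1y - s12 * s2y) / det
        b2 = (s11 * s2y - s12 * s1y) / det
        rss = np.maximum(yy - b1 * s1y - b2 * s2y, 0.0)
        yield b1, b2, rss, np.ones(s1y.shape, dtype=bool)


def _prepare_targets(Y: np.ndarray, cr: np.ndarray, w: np.ndarray):
    wc = w * cr
    s1y = wc @ Y
    yy = np.einsum("f,fv,fv->v", w, Y, Y)
    return (Y, s1y, yy)


def bfm_solve_many(Y: np.ndarray, cr: np.ndarray, basis: np.ndarray, w: np.ndarray):
    """Voxel-parallel BFM linear stage with a running minimum over theta.

    Y is (n_frames, n_voxels).  Returns (beta1, beta2, theta_index, rss,
    valid) arrays of length n_voxels; a voxel is valid when at least one
    grid value produced a non-degenerate solve and the target is not
    identically zero under the weights.
    """
    sums = _prepare_targets(Y, cr, w)
    n_vox = Y.shape[1]
    best_rss = np.full(n_vox, np.inf)
    best_idx = np.zeros(n_vox, dtype=int)
    best_b1 = np.full(n_vox, np.nan)
    best_b2 = np.full(n_vox, np.nan)
    any_ok = np.zeros(n_vox, dtype=bool)
    for j, (b1, b2, rss, ok) in enumerate(_linear_stage(sums, cr, basis, w)):
        better = ok & (rss < best_rss)
        best_rss[better] = rss[better]
        best_idx[better] = j
        best_b1[better] = b1[better]
        best_b2[better] = b2[better]
        any_ok |= ok
    nonzero = sums[2] > 0  # sum w*y^2
    valid = any_ok & nonzero & np.isfinite(best_b1)
    return best_b1, best_b2, best_idx, best_rss, valid


def fit_srtm_bfm(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    grid: ThetaGrid = ThetaGrid(),
    weights="uniform",
) -> SRTMFitResult:
    """Basis-function SRTM fit of one time-activity curve.

    For every grid theta the two-parameter weighted linear problem
    C_T ~ beta1*C_R + beta2*B_theta is solved; the theta minimising the
    weighted RSS wins (ties break to the smallest theta).  Returns
    R1 = beta1, k2a = theta*, k2 = beta2 + beta1*theta* and the full RSS
    profile.  Negative beta2 or BP_ND are returned as-is and flagged in
    ``diagnostics`` — no clamping.
    """
    if not target.schedule.same_grid(ref.schedule):
        raise ScheduleError("target and reference are on different frame schedules")
    n = target.schedule.n_frames
    if n < 3:
        raise InsufficientDataError(f"{n} frames cannot constrain a 2-parameter linear stage")
    w = _resolve_weights(weights, target.schedule)
    basis = build_basis(ref, grid)
    thetas = grid.values
    cr = ref.activity
    sums = _prepare_targets(target.activity[:, None], cr, w)
    profile = np.empty(grid.n_bases)
    b1s = np.empty(grid.n_bases)
    b2s = np.empty(grid.n_bases)
    for j, (b1, b2, rss, ok) in enumerate(_linear_stage(sums, cr, basis, w)):
        profile[j] = rss[0]
        b1s[j] = b1[0]
        b2s[j] = b2[0]
    if not np.any(np.isfinite(profile)):
        raise SingularFitError("degenerate design: reference or basis curves carry no signal")
    j_star = int(np.argmin(profile))  # first minimum -> smallest theta on ties
    theta = float(thetas[j_star])
    b1, b2 = float(b1s[j_star]), float(b2s[j_star])
    k2 = b2 + b1 * theta
    params = SRTMParameters(r1=b1, k2=k2, k2a=theta)
    diagnostics = {
        "negative_beta2": b2 < 0,
        "negative_bp": params.bp_nd < 0,
        "theta_at_boundary": j_star in (0, grid.n_bases - 1),
        "weights": weights if isinstance(weights, str) else "custom",
    }
    return SRTMFitResult(
        params=params,
        coefficients=(b1, b2),
        rss=float(profile[j_star]),
        chosen_index=j_star,
        rss_profile=profile,
        diagnostics=diagnostics,
    )


def fit_srtm_nls(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    init: Optional[SRTMParameters] = None,
    weights="uniform",
) -> SRTMFitResult:
    """Weighted nonlinear least-squares SRTM fit (independent of the BFM).

    Fits (R1, k2, k2a) directly with a trust-region reflective solver,
    recomputing the convolution at every iterate.  Serves as the oracle
    for validating the basis-function route; on noiseless SRTM data it
    recovers the generating parameters to optimiser tolerance.
    """
    if not target.schedule.same_grid(ref.schedule):
        raise ScheduleError("target and reference are on different frame schedules")
    if target.schedule.n_frames < 4:
        raise InsufficientDataError("need at least 4 frames for a 3-parameter fit")
    if init is None:
        init = SRTMParameters(r1=1.0, k2=0.15, k2a=0.15)
    if init.k2a <= 0:
        raise ParameterError("initial k2a must be positive")
    w = _resolve_weights(weights, target.schedule)
    sw = np.sqrt(w)
    y = target.activity

    def residual(x):
        r1, k2, k2a = x
        conv = exp_convolve(ref, k2a)
        model = r1 * ref.activity + (k2 - r1 * k2a) * conv
        return sw * (model - y)

    res = least_squares(
        residual,
        x0=[init.r1, init.k2, init.k2a],
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e3]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if res.status <= 0:
        raise ConvergenceError(
            f"nonlinear SRTM fit did not converge: {res.message}", final_params=res.x
        )
    r1, k2, k2a = res.x
    params = SRTMParameters(r1=float(r1), k2=float(k2), k2a=float(k2a))
    return SRTMFitResult(
        params=params,
        coefficients=(float(r1), float(k2 - r1 * k2a)),
        rss=float(res.cost * 2.0),
        chosen_index=None,
        rss_profile=None,
        diagnostics={"converged": True, "nfev": res.nfev, "status": res.status},
    )
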