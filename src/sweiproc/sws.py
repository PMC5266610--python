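"""Group shear wave speed estimation by time-of-flight methods.

The estimators consume 2-D (lateral × slow time) motion data obtained by
axially averaging the 3-D field over the push beam's depth of field
(8F²λ around the focal depth) and excluding lateral positions inside the
excitation beamwidth (≈ Fλ), where diffraction in the shear-wave near
field makes arrival times early and biases regression speeds downward.

Three methods are provided:

* arrival-time linear regression — arrival per position from the time of
  peak displacement, time of peak particle velocity, or cross-correlation
  of adjacent traces; speed is the inverse slope of the ordinary
  least-squares fit of arrival time on position;
* RANSAC — robust line fitting by repeated 2-point minimal sets and
  consensus maximisation, reporting the inlier fraction for quality
  control;
* Radon-sum trajectory detection — integrate the (rectified) space–time
  signal along candidate straight trajectories between a fixed start and
  end position over a grid of start/end times (time-upsampled), and take
  the speed of the peak-sum trajectory.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .datatypes import (ArrivalTimeProfile, MotionField, Q_DIFFERENTIAL,
                        Q_DISPLACEMENT, Q_VELOCITY, SWSEstimate)
from .errors import ParameterError, StateError
from .motion import displacement_to_velocity

FEATURES = ("peak_displacement", "peak_velocity", "xcorr")


@dataclass(frozen=True)
class RoiSpec:
    """Axial/lateral region of interest for the space–time projection.

    dof_span defaults (by the caller) to 8F²λ around the push focal depth;
    lateral_min is typically at least the excitation beamwidth Fλ away
    from the push origin.
    """

    focal_depth: float
    dof_span: float
    lateral_min: float
    lateral_max: float

    def __post_init__(self):
        if self.dof_span <= 0:
            raise ParameterError("dof_span must be positive")
        if not (self.lateral_min < self.lateral_max):
            raise ParameterError("need lateral_min < lateral_max")


@dataclass(frozen=True)
class RadonConfig:
    """Radon-sum trajectory search configuration.

    Trajectories run from (x_start, t_s) to (x_end, t_e) with t_s, t_e on
    the time-upsampled lattice and implied speed
    (x_end − x_start)/(t_e − t_s) inside speed_range (m/s).
    """

    x_start: float
    x_end: float
    time_upsample: int = 10
    speed_range: tuple = (0.25, 10.0)
    rectify: bool = True

    def __post_init__(self):
        if not (self.x_start < self.x_end):
            raise ParameterError("need x_start < x_end")
        if self.time_upsample < 1:
            raise ParameterError("time_upsample must be >= 1")
        lo, hi = self.speed_range
        if not (0 < lo < hi):
            raise ParameterError("speed_range must be positive and increasing")


def project_to_spacetime(motion: MotionField, roi: RoiSpec) -> MotionField:
    """Project a 3-D motion field to 2-D (lateral × time) over the ROI.

    Unweighted mean over axial samples within focal_depth ± dof_span/2;
    lateral positions outside [lateral_min, lateral_max] are dropped.
    2-D input skips the axial step and only applies the lateral window.
    """
    x = motion.lateral_positions
    # the near-field bound is strict: a track location at exactly the
    # excitation beamwidth still sits inside the shear-wave near field
    lat_keep = (x > roi.lateral_min) & (x <= roi.lateral_max)
    if np.sum(lat_keep) < 2:
        raise ParameterError(
            f"lateral window [{roi.lateral_min}, {roi.lateral_max}] m keeps "
            f"{int(np.sum(lat_keep))} position(s); need at least 2")
    if motion.data.ndim == 3:
        z = motion.axial_positions
        lo = roi.focal_depth - roi.dof_span / 2.0
        hi = roi.focal_depth + roi.dof_span / 2.0
        ax_keep = (z >= lo) & (z <= hi)
        if not np.any(ax_keep):
            raise ParameterError(
                f"axial window [{lo}, {hi}] m selects no samples "
                f"(data spans [{z.min()}, {z.max()}] m)")
        data = motion.data[ax_keep][:, lat_keep, :].mean(axis=0)
    else:
        data = motion.data[lat_keep, :]
    out = MotionField(data=data, quantity=motion.quantity,
                      times=motion.times.copy(),
                      lateral_positions=x[lat_keep],
                      frame_labels=(motion.frame_labels.copy()
                                    if motion.frame_labels is not None else None),
                      interpolated_mask=motion.interpolated_mask.copy(),
                      provenance=list(motion.provenance))
    out.log("project_to_spacetime", focal_depth=roi.focal_depth,
            dof_span=roi.dof_span, lateral_min=roi.lateral_min,
            lateral_max=roi.lateral_max)
    return out


def _refine_peak(t_fine: np.ndarray, y_fine: np.ndarray) -> tuple:
    """Earliest-maximum index with 3-point parabolic refinement."""
    i = int(np.argmax(y_fine))  # argmax returns the earliest tie
    denom = 0.0
    if 0 < i < len(y_fine) - 1:
        denom = y_fine[i - 1] - 2.0 * y_fine[i] + y_fine[i + 1]
    if denom != 0.0:
        delta = 0.5 * (y_fine[i - 1] - y_fine[i + 1]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    dt_fine = t_fine[1] - t_fine[0]
    return t_fine[i] + delta * dt_fine, float(y_fine[i])


def extract_arrival_times(spacetime: MotionField, feature: str,
                          time_upsample: int = 10) -> ArrivalTimeProfile:
    """Shear-wave arrival time versus lateral position.

    peak_displacement / peak_velocity: per-position global maximum along
    time on a cubic-spline-upsampled grid (factor ``time_upsample``) with
    3-point parabolic refinement; velocity is obtained by differentiation
    when the input carries displacement. xcorr: normalized
    cross-correlation lag between adjacent positions' traces (same
    sub-sample refinement), accumulated and anchored at the first
    position's peak time. Positions with non-positive peak amplitude are
    dropped with a warning.
    """
    if feature not in FEATURES:
        raise ParameterError(f"feature must be one of {FEATURES}")
    if not spacetime.is_projected:
        raise ParameterError("extract_arrival_times expects 2-D (lateral x "
                             "time) data; run project_to_spacetime first")
    if time_upsample < 1:
        raise ParameterError("time_upsample must be >= 1")
    st = spacetime
    if feature == "peak_velocity" and st.quantity in (Q_DISPLACEMENT,
                                                      Q_DIFFERENTIAL):
        st = displacement_to_velocity(st)
    dt = st.dt
    t = st.times
    n_fine = (len(t) - 1) * time_upsample + 1
    t_fine = np.linspace(t[0], t[-1], n_fine)
    traces = CubicSpline(t, st.data, axis=-1)(t_fine)  # (lateral, fine)

    x = st.lateral_positions
    if feature in ("peak_displacement", "peak_velocity"):
        arrivals, quality, keep = [], [], []
        for j in range(len(x)):
            t_peak, amp = _refine_peak(t_fine, traces[j])
            if amp <= 0:
                warnings.warn(f"no positive wave peak at x = {x[j]*1e3:.2f} mm; "
                              "position dropped", stacklevel=2)
                continue
            arrivals.append(t_peak)
            quality.append(amp)
            keep.append(j)
        if len(keep) < 2:
            raise StateError("fewer than 2 positions with a detectable wave")
        return ArrivalTimeProfile(lateral_positions=x[keep],
                                  arrival_times=np.array(arrivals),
                                  feature=feature,
                                  quality=np.array(quality))

    # xcorr feature: adjacent-trace lags, accumulated
    t0_peak, amp0 = _refine_peak(t_fine, traces[0])
    if amp0 <= 0:
        raise StateError("first trace carries no positive wave peak")
    arrivals = [t0_peak]
    quality = [amp0]
    dt_fine = t_fine[1] - t_fine[0]
    for j in range(1, len(x)):
        # no mean removal here: with 'full' overlap a constant offset makes
        # the correlation asymmetric around its peak and biases the
        # parabolic refinement; the motion filter removes DC upstream
        a = traces[j - 1]
        b = traces[j]
        cc = np.correlate(b, a, mode="full")
        norm = np.sqrt(np.sum(a**2) * np.sum(b**2))
        cc = cc / norm if norm > 0 else cc
        lags = (np.arange(len(cc)) - (len(a) - 1)) * dt_fine
        lag, peak_cc = _refine_peak(lags, cc)
        arrivals.append(arrivals[-1] + lag)
        quality.append(peak_cc)
    return ArrivalTimeProfile(lateral_positions=x.copy(),
                              arrival_times=np.array(arrivals),
                              feature="xcorr", quality=np.array(quality))


def _failure(method: str, message: str, n: int) -> SWSEstimate:
    return SWSEstimate(sws=float("nan"), intercept=float("nan"), method=method,
                       success=False, message=message, n_points=n)


def fit_sws_regression(profile: ArrivalTimeProfile,
                       roi: Optional[RoiSpec] = None) -> SWSEstimate:
    """Ordinary least-squares arrival-time regression.

    Fits arrival time on lateral position; the group speed is the inverse
    slope. Reports R² and a 95 % confidence interval propagated to the
    speed from the slope standard error to first order. A non-positive
    slope yields a flagged failure result rather than an exception. Fewer
    than 6 points triggers a guidance warning (use ≥ 6 positions covering
    several millimetres).
    """
    n = len(profile)
    if n < 3:
        raise ParameterError("need at least 3 points for a regression")
    if n < 6:
        warnings.warn("fewer than 6 lateral positions: regression is "
                      "sensitive to outliers", stacklevel=2)
    res = stats.linregress(profile.lateral_positions, profile.arrival_times)
    if res.slope <= 0:
        return _failure("regression", "non-positive arrival-time slope "
                        "(no rightward-propagating wave detected)", n)
    sws = 1.0 / res.slope
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else float("nan")
    dsws = tcrit * res.stderr / res.slope**2
    return SWSEstimate(sws=sws, intercept=res.intercept, method="regression",
                       r_squared=res.rvalue**2,
                       ci95=(sws - dsws, sws + dsws), roi=roi, n_points=n)


def fit_sws_ransac(profile: ArrivalTimeProfile, threshold: float,
                   iterations: int = 2000, seed: int = 0,
                   roi: Optional[RoiSpec] = None) -> SWSEstimate:
    """RANSAC arrival-time line fit.

    Repeatedly draws a 2-point minimal set, forms the line through it, and
    collects the consensus set of points with |time residual| ≤
    ``threshold`` (seconds; one frame interval is a good default). The
    largest consensus wins (ties: lowest consensus RMS residual); the
    final speed is an OLS refit on that consensus set, and the inlier
    fraction is reported for quality control. Deterministic for a fixed
    seed.
    """
    n = len(profile)
    if n < 4:
        raise ParameterError("RANSAC needs at least 4 points")
    if threshold <= 0 or iterations < 1:
        raise ParameterError("threshold must be > 0 and iterations >= 1")
    x = profile.lateral_positions
    t = profile.arrival_times
    rng = np.random.default_rng(seed)
    best_count = 0
    best_rms = np.inf
    best_mask = None
    for _ in range(iterations):
        i, j = rng.choice(n, size=2, replace=False)
        if x[i] == x[j]:
            continue
        slope = (t[j] - t[i]) / (x[j] - x[i])
        intercept = t[i] - slope * x[i]
        resid = np.abs(t - (intercept + slope * x))
        mask = resid <= threshold
        count = int(mask.sum())
        if count < 3:
            continue
        rms = float(np.sqrt(np.mean(resid[mask] ** 2)))
        if count > best_count or (count == best_count and rms < best_rms):
            best_count, best_rms, best_mask = count, rms, mask
    if best_mask is None:
        return _failure("ransac", "no consensus set of >= 3 points", n)
    sub = ArrivalTimeProfile(lateral_positions=x[best_mask],
                             arrival_times=t[best_mask],
                             feature=profile.feature)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = fit_sws_regression(sub, roi=roi)
    if not ols.success:
        return _failure("ransac", ols.message, n)
    return SWSEstimate(sws=ols.sws, intercept=ols.intercept, method="ransac",
                       r_squared=ols.r_squared, ci95=ols.ci95,
                       inlier_fraction=best_count / n, roi=roi, n_points=n)


def radon_sum_surface(spacetime: MotionField, cfg: RadonConfig):
    """Radon sums for every feasible (start time, end time) trajectory.

    Returns (t_start grid, t_end grid, sums, speeds) where infeasible
    pairs (speed outside ``speed_range`` or non-positive transit time)
    hold NaN. Time upsampling by cubic spline; signal values along each
    trajectory are linearly interpolated in time at every lateral
    position inside [x_start, x_end] and summed.
    """
    if not spacetime.is_projected:
        raise ParameterError("radon estimation expects 2-D data")
    x = spacetime.lateral_positions
    if not (x.min() <= cfg.x_start < cfg.x_end <= x.max()):
        raise ParameterError("x_start/x_end must lie within the lateral span")
    sel = (x >= cfg.x_start) & (x <= cfg.x_end)
    if np.sum(sel) < 2:
        raise ParameterError("fewer than 2 lateral positions in [x_start, x_end]")
    xs = x[sel]
    sig = spacetime.data[sel, :]
    if cfg.rectify:
        sig = np.abs(sig)
    t = spacetime.times
    spacetime.dt  # uniformity check
    n_fine = (len(t) - 1) * cfg.time_upsample + 1
    t_fine = np.linspace(t[0], t[-1], n_fine)
    traces = CubicSpline(t, sig, axis=-1)(t_fine)

    span = cfg.x_end - cfg.x_start
    ts = t_fine[:, None]          # start times
    te = t_fine[None, :]          # end times
    transit = te - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = span / transit
    lo, hi = cfg.speed_range
    feasible = (transit > 0) & (speeds >= lo) & (speeds <= hi)
    sums = np.full(feasible.shape, np.nan)
    if not np.any(feasible):
        raise ParameterError("no feasible trajectory: widen speed_range or the "
                             "time window")
    idx = np.nonzero(feasible)
    ts_f = t_fine[idx[0]]
    te_f = t_fine[idx[1]]
    acc = np.zeros(len(ts_f))
    for j, xj in enumerate(xs):
        frac = (xj - cfg.x_start) / span
        tj = ts_f + frac * (te_f - ts_f)
        acc += np.interp(tj, t_fine, traces[j])
    sums[idx] = acc
    return t_fine, t_fine, sums, np.where(feasible, speeds, np.nan)


def fit_sws_radon(spacetime: MotionField, cfg: RadonConfig,
                  roi: Optional[RoiSpec] = None) -> SWSEstimate:
    """Shear-wave trajectory detection by peak Radon sum.

    The optimal trajectory maximises the integrated (rectified) signal;
    ties go to the slowest speed. A spatially uniform field produces a
    flat Radon surface (peak-to-median ratio < 1.5) and yields a flagged
    failure result.
    """
    _, _, sums, speeds = radon_sum_surface(spacetime, cfg)
    finite = np.isfinite(sums)
    vals = sums[finite]
    peak = vals.max()
    med = np.median(vals)
    if med > 0 and peak / med < 1.5:
        return _failure("radon", "flat Radon surface (peak/median "
                        f"{peak/med:.2f} < 1.5): no trajectory detected",
                        int(finite.sum()))
    best = np.nanmax(sums)
    cand = np.isclose(sums, best, rtol=1e-12, atol=0.0) & finite
    v = float(np.nanmin(speeds[cand]))  # tie-break: slowest speed
    return SWSEstimate(sws=v, intercept=float("nan"), method="radon",
                       quality=float(best), roi=roi,
                       n_points=int(finite.sum()))


def estimate_sws(spacetime: MotionField, method: str = "regression",
                 feature: str = "peak_displacement", time_upsample: int = 10,
                 roi: Optional[RoiSpec] = None,
                 ransac_threshold: Optional[float] = None,
                 ransac_iterations: int = 2000, seed: int = 0,
                 radon_config: Optional[RadonConfig] = None) -> SWSEstimate:
    """One-call front end dispatching to the three TOF estimators."""
    if method == "radon":
        if radon_config is None:
            x = spacetime.lateral_positions
            radon_config = RadonConfig(x_start=float(x[0]), x_end=float(x[-1]),
                                       time_upsample=time_upsample)
        return fit_sws_radon(spacetime, radon_config, roi=roi)
    profile = extract_arrival_times(spacetime, feature, time_upsample)
    if method == "regression":
        return fit_sws_regression(profile, roi=roi)
    if method == "ransac":
        thr = ransac_threshold if ransac_threshold is not None else spacetime.dt
        return fit_sws_ransac(profile, thr, iterations=ransac_iterations,
                              seed=seed, roi=roi)
    raise ParameterError("method must be regression|ransac|radon")
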