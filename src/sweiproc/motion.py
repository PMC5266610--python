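"""Tissue motion estimation from beamformed IQ or RF ensembles.

Two families of time-delay estimators are provided:

* phase-shift autocorrelators on IQ data — the 1-D (Kasai) estimator, with
  fixed, progressive and Doppler-style ensemble-averaged referencing, and
  the 2-D (Loupas) estimator that additionally tracks the local RF centre
  frequency along fast time;
* normalized cross-correlation (NXcorr) on RF data, with cubic-spline
  upsampling and parabolic sub-sample peak refinement, together with the
  IQ→RF remodulation needed to feed it from baseband data.

Phase-to-displacement convention (package-wide contract): displacement
away from the transducer is positive and rotates the IQ phase by
+4π·fc·u/c, so the estimators return u = c/(4π·fc)·arg(R) with R the
lag autocorrelation Σ_m x*(m, ref)·x(m, i) over an M-sample axial kernel.
The four-quadrant phase confines estimates to |u| ≤ c/(4·fc) = λ/4
(half the two-way path wavelength); displacements beyond that bound wrap.

Conversions between displacement and particle velocity (differentiation /
accumulation along slow time) live here as well.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .datatypes import (IQEnsemble, MotionField, Q_DIFFERENTIAL,
                        Q_DISPLACEMENT, Q_VELOCITY, RFEnsemble)
from .errors import ParameterError, StateError


@dataclass(frozen=True)
class KasaiConfig:
    """Phase-shift estimator configuration.

    kernel_length: axial kernel M (samples); stride between kernels
    defaults to max(1, M//2). reference selects fixed (displacement
    relative to a pre-push reference frame), progressive (per-frame
    differential displacement) or ensemble (Doppler-style average over
    ensemble_length adjacent-frame products) referencing.
    """

    kernel_length: int = 8
    reference: str = "fixed"
    reference_frame: Optional[int] = None
    ensemble_length: int = 2
    stride: Optional[int] = None

    def __post_init__(self):
        if self.kernel_length < 1:
            raise ParameterError("kernel_length must be >= 1")
        if self.reference not in ("fixed", "progressive", "ensemble"):
            raise ParameterError("reference must be fixed|progressive|ensemble")
        if self.reference == "ensemble" and self.ensemble_length < 2:
            raise ParameterError("ensemble_length must be >= 2")
        if self.stride is not None and self.stride < 1:
            raise ParameterError("stride must be >= 1")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None \
            else max(1, self.kernel_length // 2)


def _window_starts(n_axial: int, m: int, stride: int) -> np.ndarray:
    if m > n_axial:
        raise ParameterError(f"kernel_length {m} exceeds axial extent {n_axial}")
    return np.arange(0, n_axial - m + 1, stride)


def _window_sums(prod: np.ndarray, starts: np.ndarray, m: int) -> np.ndarray:
    """Sum `prod` over axial kernels [s, s+m) for every start s.

    prod: (axial, ...) -> (n_windows, ...), via cumulative sums.
    """
    c = np.cumsum(prod, axis=0)
    c = np.concatenate([np.zeros_like(c[:1]), c], axis=0)
    return c[starts + m] - c[starts]


def _phase_to_disp(r: np.ndarray, c: float, fc: float) -> np.ndarray:
    u = c / (4.0 * np.pi * fc) * np.angle(r)
    u = np.where(np.abs(r) == 0.0, np.nan, u)  # undefined phase mask
    return u


def _axial_centres(starts: np.ndarray, m: int, interval: float) -> np.ndarray:
    return (starts + (m - 1) / 2.0) * interval


def kasai_displacement(iq: IQEnsemble, cfg: KasaiConfig = KasaiConfig()
                       ) -> MotionField:
    """1-D autocorrelation (Kasai) phase-shift displacement estimate.

    Returns a 3-D MotionField (axial kernel centre x lateral x frame).
    Fixed referencing yields absolute displacement (zero at the reference
    frame); progressive referencing yields per-frame differential
    displacement (zero at the first frame); ensemble referencing yields a
    single Doppler-style average of the per-interval displacement over
    ``ensemble_length`` frames.
    """
    x = iq.data
    n_ax, n_lat, n_fr = x.shape
    m = cfg.kernel_length
    starts = _window_starts(n_ax, m, cfg.effective_stride)
    axial = _axial_centres(starts, m, iq.axial_interval)

    if cfg.reference == "fixed":
        ref = cfg.reference_frame if cfg.reference_frame is not None \
            else iq.reference_frame_index()
        if not (0 <= ref < n_fr):
            raise ParameterError(f"reference_frame {ref} out of range")
        prod = np.conj(x[:, :, ref:ref + 1]) * x  # (ax, lat, fr)
        r = _window_sums(prod, starts, m)
        u = _phase_to_disp(r, iq.sound_speed, iq.fc)
        quantity = Q_DISPLACEMENT
        times = iq.frame_times
        labels = iq.frame_labels
    elif cfg.reference == "progressive":
        prod = np.conj(x[:, :, :-1]) * x[:, :, 1:]
        r = _window_sums(prod, starts, m)
        du = _phase_to_disp(r, iq.sound_speed, iq.fc)
        u = np.concatenate([np.zeros_like(du[:, :, :1]), du], axis=2)
        quantity = Q_DIFFERENTIAL
        times = iq.frame_times
        labels = iq.frame_labels
    else:  # ensemble (Doppler-style averaging)
        n = cfg.ensemble_length
        if n > n_fr:
            raise ParameterError("ensemble_length exceeds frame count")
        prod = np.conj(x[:, :, :n - 1]) * x[:, :, 1:n]
        r = _window_sums(prod, starts, m).sum(axis=2, keepdims=True)
        u = _phase_to_disp(r, iq.sound_speed, iq.fc)
        quantity = Q_DIFFERENTIAL
        times = np.array([iq.frame_times[:n].mean()])
        labels = None

    mf = MotionField(data=u, quantity=quantity, times=times,
                     lateral_positions=iq.lateral_positions.copy(),
                     axial_positions=axial,
                     frame_labels=None if labels is None else labels.copy(),
                     provenance=list(iq.provenance))
    mf.log("kasai_displacement", kernel_length=m, reference=cfg.reference,
           stride=cfg.effective_stride)
    return mf


def loupas_displacement(iq: IQEnsemble, cfg: KasaiConfig = KasaiConfig()
                        ) -> MotionField:
    """2-D autocorrelation (Loupas) displacement estimate.

    Extends the 1-D phase-shift estimator by estimating the mean RF
    frequency at each axial kernel from the fast-time lag-one
    autocorrelation phase, and normalising the slow-time phase by that
    frequency instead of the nominal demodulation frequency. When the
    data's RF centre frequency equals ``fc`` the estimate reduces to the
    Kasai estimate.
    """
    if cfg.kernel_length < 2:
        raise ParameterError("Loupas needs kernel_length >= 2 for the axial lag")
    if cfg.reference == "ensemble":
        raise ParameterError("ensemble referencing is not defined for Loupas here")
    x = iq.data
    n_ax, n_lat, n_fr = x.shape
    m = cfg.kernel_length
    starts = _window_starts(n_ax, m, cfg.effective_stride)
    axial = _axial_centres(starts, m, iq.axial_interval)
    dt_fast = 2.0 * iq.axial_interval / iq.sound_speed

    # mean RF frequency per kernel/lateral/frame from the axial lag-1 phase:
    # the kernel [a, a+M) contains M-1 lag-one products
    prod_ax = np.conj(x[:-1]) * x[1:]
    r_ax = _window_sums(prod_ax, starts, m - 1)
    f_rf = iq.fc + np.angle(r_ax) / (2.0 * np.pi * dt_fast)

    if cfg.reference == "fixed":
        ref = cfg.reference_frame if cfg.reference_frame is not None \
            else iq.reference_frame_index()
        prod = np.conj(x[:, :, ref:ref + 1]) * x
        r = _window_sums(prod, starts, m)
        # average the RF frequency estimate of reference and tracked frames
        f_est = 0.5 * (f_rf + f_rf[:, :, ref:ref + 1])
        u = iq.sound_speed / (4.0 * np.pi * f_est) * np.angle(r)
        u = np.where(np.abs(r) == 0.0, np.nan, u)
        quantity = Q_DISPLACEMENT
    else:  # progressive
        prod = np.conj(x[:, :, :-1]) * x[:, :, 1:]
        r = _window_sums(prod, starts, m)
        f_est = 0.5 * (f_rf[:, :, :-1] + f_rf[:, :, 1:])
        du = iq.sound_speed / (4.0 * np.pi * f_est) * np.angle(r)
        du = np.where(np.abs(r) == 0.0, np.nan, du)
        u = np.concatenate([np.zeros_like(du[:, :, :1]), du], axis=2)
        quantity = Q_DIFFERENTIAL

    mf = MotionField(data=u, quantity=quantity, times=iq.frame_times.copy(),
                     lateral_positions=iq.lateral_positions.copy(),
                     axial_positions=axial,
                     frame_labels=(iq.frame_labels.copy()
                                   if iq.frame_labels is not None else None),
                     provenance=list(iq.provenance))
    mf.log("loupas_displacement", kernel_length=m, reference=cfg.reference)
    return mf


def remodulate_to_rf(iq: IQEnsemble, output_fs: float) -> RFEnsemble:
    """Re-modulate baseband IQ to RF by upsampling and carrier insertion.

    Each axial line is FFT-resampled from the IQ fast-time rate
    c/(2·axial_interval) to ``output_fs``, multiplied by the fc carrier,
    and the real part taken: rf(t) = Re{ iq_up(t)·exp(i·2π·fc·t) }.
    Demodulating the result (:func:`demodulate_to_iq`) reproduces the
    input band to resampling tolerance.
    """
    fs_iq = iq.sound_speed / (2.0 * iq.axial_interval)
    if output_fs < 4.0 * iq.fc:
        raise ParameterError("output_fs must be at least 4·fc to represent the "
                             "modulated band")
    n_ax = iq.data.shape[0]
    n_out = int(round(n_ax * output_fs / fs_iq))
    fs_actual = n_out * fs_iq / n_ax
    up = sps.resample(iq.data, n_out, axis=0)
    t = np.arange(n_out) / fs_actual
    # Snap the carrier to the nearest frequency with an integer number of
    # cycles over the record so the modulated image stays spectrally clean
    # (exact when the axial interval is exactly λ/4; within fs_iq/(2·n_ax)
    # of fc otherwise). Correlation tracking is insensitive to the snap;
    # the carrier actually used is stored in the output's fc.
    duration = n_ax / fs_iq
    fc_used = round(iq.fc * duration) / duration
    rf = np.real(up * np.exp(1j * 2.0 * np.pi * fc_used * t)[:, None, None])
    return RFEnsemble(data=rf, fs=fs_actual, fc=fc_used,
                      sound_speed=iq.sound_speed,
                      lateral_positions=iq.lateral_positions.copy(),
                      frame_times=iq.frame_times.copy(),
                      frame_labels=iq.frame_labels.copy(),
                      provenance=list(iq.provenance)
                      + [{"op": "remodulate_to_rf",
                          "config": {"output_fs": fs_actual}}])


def demodulate_to_iq(rf: RFEnsemble, n_out: int,
                     axial_interval: float) -> IQEnsemble:
    """Inverse of :func:`remodulate_to_rf`: mix down, low-pass, resample."""
    n_ax = rf.data.shape[0]
    t = np.arange(n_ax) / rf.fs
    analytic = rf.data * (2.0 * np.exp(-1j * 2.0 * np.pi * rf.fc * t)[:, None, None])
    spec = np.fft.fft(analytic, axis=0)
    f = np.fft.fftfreq(n_ax, 1.0 / rf.fs)
    spec[np.abs(f) >= rf.fc] = 0.0  # keep the baseband image only
    base = np.fft.ifft(spec, axis=0)
    iq = sps.resample(base, n_out, axis=0)
    return IQEnsemble(data=iq, fc=rf.fc, sound_speed=rf.sound_speed,
                      axial_interval=axial_interval,
                      lateral_positions=rf.lateral_positions.copy(),
                      frame_times=rf.frame_times.copy(),
                      frame_labels=rf.frame_labels.copy(),
                      provenance=list(rf.provenance)
                      + [{"op": "demodulate_to_iq", "config": {}}])


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of the extremum around index i via a 3-point parabola."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def nxcorr_displacement(rf: RFEnsemble, kernel_length: int, search: int,
                        upsample_factor: int = 10,
                        reference_frame: int = 0) -> MotionField:
    """Normalized cross-correlation displacement on RF data.

    For every axial kernel, lateral position and frame, the reference-frame
    kernel is cross-correlated against the tracked frame over lags within
    ±``search`` samples after cubic-spline upsampling of both by
    ``upsample_factor``; the correlation peak is refined by a 3-point
    parabolic fit. displacement = lag·c/(2·fs·upsample_factor). The peak
    correlation coefficient is retained per sample as a quality weight
    (``provenance`` carries it under 'nxcorr_quality' on the returned
    field's attribute ``quality``).
    """
    if upsample_factor < 1:
        raise ParameterError("upsample_factor must be >= 1")
    x = rf.data
    n_ax, n_lat, n_fr = x.shape
    k, s = int(kernel_length), int(search)
    if k < 3 or s < 1:
        raise ParameterError("kernel_length >= 3 and search >= 1 required")
    starts = np.arange(s, n_ax - k - s + 1, max(1, k // 2))
    if len(starts) == 0:
        raise ParameterError("kernel + search window exceeds axial extent")
    u_fs = rf.fs * upsample_factor
    fine = np.arange(0, (k + 2 * s - 1) * upsample_factor + 1) / u_fs
    n_k_up = (k - 1) * upsample_factor + 1

    u = np.full((len(starts), n_lat, n_fr), np.nan)
    quality = np.full((len(starts), n_lat, n_fr), np.nan)
    t_seg = np.arange(k + 2 * s) / rf.fs
    t_ker = np.arange(k) / rf.fs
    for w, a in enumerate(starts):
        for j in range(n_lat):
            ref_seg = x[a:a + k, j, reference_frame]
            if np.ptp(ref_seg) == 0.0:
                continue  # flat kernel: correlation undefined
            ref_up = CubicSpline(t_ker, ref_seg)(
                np.arange(n_k_up) / u_fs)
            ref_up = ref_up - ref_up.mean()
            ref_norm = np.sqrt(np.sum(ref_up**2))
            for i in range(n_fr):
                seg = x[a - s:a + k + s, j, i]
                if np.ptp(seg) == 0.0:
                    continue
                seg_up = CubicSpline(t_seg, seg)(fine)
                n_lags = len(seg_up) - n_k_up + 1
                cc = np.empty(n_lags)
                for lag in range(n_lags):
                    win = seg_up[lag:lag + n_k_up]
                    win = win - win.mean()
                    denom = ref_norm * np.sqrt(np.sum(win**2))
                    cc[lag] = np.dot(ref_up, win) / denom if denom > 0 else 0.0
                peak = int(np.argmax(cc))
                # a perfect match needs no sub-sample refinement
                delta = 0.0 if cc[peak] >= 1.0 - 1e-9 \
                    else _parabolic_refine(cc, peak)
                # lag index s·U corresponds to zero shift
                shift = (peak + delta - s * upsample_factor) / u_fs
                u[w, j, i] = shift * rf.sound_speed / 2.0
                quality[w, j, i] = cc[peak]

    axial = (starts + (k - 1) / 2.0) / rf.fs * rf.sound_speed / 2.0
    mf = MotionField(data=u, quantity=Q_DISPLACEMENT,
                     times=rf.frame_times.copy(),
                     lateral_positions=rf.lateral_positions.copy(),
                     axial_positions=axial,
                     frame_labels=(rf.frame_labels.copy()
                                   if rf.frame_labels is not None else None),
                     provenance=list(rf.provenance))
    mf.log("nxcorr_displacement", kernel_length=k, search=s,
           upsample_factor=upsample_factor)
    mf.quality = quality
    return mf


def displacement_to_velocity(motion: MotionField) -> MotionField:
    """Particle velocity from displacement along slow time.

    Absolute displacement is differentiated with central differences
    (one-sided at the ends) so that peak-velocity timing stays unbiased;
    differential displacement is simply divided by the frame interval.
    Requires uniform slow-time sampling (repair reverberation frames
    first).
    """
    dt = motion.dt  # raises StateError if non-uniform
    if motion.quantity == Q_VELOCITY:
        raise ParameterError("input is already velocity")
    if motion.quantity == Q_DIFFERENTIAL:
        v = motion.data / dt
    else:
        v = np.gradient(motion.data, dt, axis=-1)
    out = motion.copy_with(data=v, quantity=Q_VELOCITY)
    out.log("displacement_to_velocity", dt=dt)
    return out


def velocity_to_displacement(motion: MotionField) -> MotionField:
    """Displacement by accumulating velocity along slow time (u(t₀) = 0)."""
    dt = motion.dt
    if motion.quantity != Q_VELOCITY:
        raise ParameterError("input must be velocity")
    u = np.cumsum(motion.data, axis=-1) * dt
    u = u - u[..., :1]  # anchor u(t0) = 0
    out = motion.copy_with(data=u, quantity=Q_DISPLACEMENT)
    out.log("velocity_to_displacement", dt=dt)
    return out


def accumulate_differential(motion: MotionField) -> MotionField:
    """Absolute displacement from progressive (differential) displacement.

    u_i = Σ_{j≤i} Δu_j, anchored at zero before the first increment.
    """
    if motion.quantity != Q_DIFFERENTIAL:
        raise ParameterError("input must be differential displacement")
    u = np.cumsum(motion.data, axis=-1)
    out = motion.copy_with(data=u, quantity=Q_DISPLACEMENT)
    out.log("accumulate_differential")
    return out
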