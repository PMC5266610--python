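"""Synthetic SWEI acquisition simulator.

Every downstream stage of the pipeline is testable without a scanner:
this module generates ground-truth shear-wave motion fields with analytic
arrival times, corrupts them with the artifacts seen in practice
(push-reverberation frames, low-frequency rigid body motion, boundary
reflections), renders speckle IQ ensembles whose phase encodes the motion,
and produces point-target envelope image pairs for beam-position
calibration.

The displacement pulse is a temporal Gaussian

    u(x, t) = A · (x_ref/|x − x₀|)^p · exp(−(t − t₀ − |x − x₀|/v)² / (2σ²))

travelling laterally at the ground-truth speed v from the push origin x₀,
so the peak-displacement arrival time at position x is exactly
t₀ + |x − x₀|/v and the peak-velocity arrival is exactly σ earlier — both
available in closed form for test assertions. The geometric amplitude decay
is normalised at the reference distance x_ref = 1 mm.

IQ rendering uses a pure-phase model by default: each frame is the
reference speckle column rotated by exp(+i·4π·fc·u/c), where displacement
*away* from the transducer is positive (package-wide sign contract,
enforced by the round-trip test against the phase-shift tracker). An RF
"resample" path (:func:`render_shifted_rf_ensemble`) creates realistic
speckle shifts for correlation-based tracking tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .datatypes import (LABEL_PUSH, LABEL_REFERENCE, LABEL_TRACK,
                        IQEnsemble, MotionField, Q_DISPLACEMENT, RFEnsemble)
from .errors import ParameterError

#: lateral distance (m) at which the geometric decay factor equals 1
DECAY_REFERENCE_M = 1.0e-3


@dataclass(frozen=True)
class ShearWaveScenario:
    """Ground-truth description of one simulated shear-wave acquisition.

    true_sws: propagation speed (m/s). pulse_center_frequency documents the
    shear-wave band (Hz); the temporal shape is governed by pulse_sigma (s).
    amplitude: peak axial displacement (m) at the decay reference distance.
    decay_exponent: geometric amplitude decay power of lateral distance
    (0 = no decay, 0.5 = cylindrical-spreading-like).
    """

    true_sws: float = 1.1
    pulse_center_frequency: float = 200.0
    pulse_sigma: float = 1.0e-3
    amplitude: float = 5.0e-6
    origin_x: float = 0.0
    decay_exponent: float = 0.5
    direction: str = "rightward"
    start_time: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.true_sws <= 0:
            raise ParameterError("true_sws must be positive")
        if self.pulse_sigma <= 0:
            raise ParameterError("pulse_sigma must be positive")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")
        if self.decay_exponent < 0:
            raise ParameterError("decay_exponent must be non-negative")
        if self.direction not in ("rightward", "leftward"):
            raise ParameterError("direction must be 'rightward' or 'leftward'")

    def arrival_time(self, x) -> np.ndarray:
        """Analytic peak-displacement arrival time at lateral position(s) x."""
        return self.start_time + np.abs(np.asarray(x, float) - self.origin_x) \
            / self.true_sws

    def displacement(self, x, t) -> np.ndarray:
        """Closed-form displacement field on a (position, time) grid.

        x and t are broadcast against each other.
        """
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        d = np.abs(x - self.origin_x)
        if self.decay_exponent > 0 and np.any(d == 0):
            raise ParameterError("position coincides with the push origin; "
                                 "amplitude is singular for decay_exponent > 0")
        decay = np.ones_like(d) if self.decay_exponent == 0 \
            else (DECAY_REFERENCE_M / d) ** self.decay_exponent
        tau = t - self.start_time - d / self.true_sws
        return self.amplitude * decay * np.exp(-tau**2 / (2.0 * self.pulse_sigma**2))


@dataclass(frozen=True)
class SpeckleConfig:
    """Speckle/noise model for IQ rendering.

    fractional_bandwidth is the track pulse's −6 dB bandwidth as a fraction
    of fc; snr_db sets additive complex white noise relative to the mean
    speckle power (np.inf = noise-free).
    """

    axial_samples: int = 64
    axial_interval: float = 74.0e-6
    fractional_bandwidth: float = 0.6
    snr_db: float = np.inf
    seed: int = 0

    def __post_init__(self):
        if self.axial_samples < 4:
            raise ParameterError("axial_samples must be at least 4")
        if self.axial_interval <= 0:
            raise ParameterError("axial_interval must be positive")
        if not (0 < self.fractional_bandwidth <= 2):
            raise ParameterError("fractional_bandwidth must be in (0, 2]")


@dataclass(frozen=True)
class ArtifactSpec:
    """Phenomenological acquisition artifacts.

    reverb_frames: number of post-push frames corrupted by push-pulse
    clutter; the corruption is spatially rough noise of amplitude
    reverb_amplitude (applied to the push frames as well — no valid
    tracking exists while the push transmits). rigid_motion_*: a
    lateral-uniform low-frequency sinusoidal background displacement.
    reflection_*: a mirrored pulse launched back from a stiffness boundary.
    """

    reverb_frames: int = 0
    reverb_amplitude: float = 0.0
    rigid_motion_frequency: float = 5.0
    rigid_motion_amplitude: float = 0.0
    reflection_position: Optional[float] = None
    reflection_coefficient: float = 0.0

    def __post_init__(self):
        if self.reverb_frames < 0:
            raise ParameterError("reverb_frames must be non-negative")
        if not (0.0 <= self.reflection_coefficient <= 1.0):
            raise ParameterError("reflection_coefficient must be in [0, 1]")
        if self.rigid_motion_frequency <= 0:
            raise ParameterError("rigid_motion_frequency must be positive")


def frame_schedule(pri: float, n_reference: int = 4, n_push: int = 3,
                   n_track: int = 25, t_push: float = 0.0):
    """Uniform slow-time frame grid with labels.

    Returns (times, labels): ``n_reference`` reference frames, then
    ``n_push`` push frames starting at ``t_push``, then ``n_track`` track
    frames, all at interval ``pri``.
    """
    if pri <= 0:
        raise ParameterError("pri must be positive")
    n = n_reference + n_push + n_track
    times = t_push + (np.arange(n) - n_reference) * pri
    labels = np.array([LABEL_REFERENCE] * n_reference + [LABEL_PUSH] * n_push
                      + [LABEL_TRACK] * n_track, dtype=object)
    return times, labels


def default_lateral_positions(start: float = 0.5e-3, stop: float = 5.0e-3,
                              step: float = 0.5e-3) -> np.ndarray:
    """Track beam positions mirroring the reference acquisition: signed
    lateral distance from the push origin, 0.5–5 mm in 0.5 mm steps."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def simulate_shear_wave_motion(scenario: ShearWaveScenario,
                               lateral_positions: Sequence[float],
                               frame_times: Sequence[float],
                               frame_labels: Optional[Sequence[str]] = None,
                               ) -> MotionField:
    """Noise-free ground-truth displacement field (lateral x slow time)."""
    x = np.asarray(lateral_positions, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    if scenario.direction == "rightward":
        if np.any(x < scenario.origin_x):
            raise ParameterError("rightward propagation: lateral positions must "
                                 "lie at or beyond the push origin")
    else:
        if np.any(x > scenario.origin_x):
            raise ParameterError("leftward propagation: lateral positions must "
                                 "lie at or before the push origin")
    u = scenario.displacement(x[:, None], t[None, :])
    labels = None if frame_labels is None else np.asarray(frame_labels,
                                                          dtype=object)
    mf = MotionField(data=u, quantity=Q_DISPLACEMENT, times=t,
                     lateral_positions=x, frame_labels=labels)
    mf.log("simulate_shear_wave_motion",
           true_sws=scenario.true_sws, seed=scenario.seed)
    return mf


def artifact_field(motion: MotionField, spec: ArtifactSpec,
                   scenario: ShearWaveScenario) -> np.ndarray:
    """The additive artifact field alone, same shape as ``motion.data``.

    ``add_artifacts`` returns exactly ``clean + artifact_field`` so that the
    superposition property can be asserted bit-for-bit.
    """
    x = motion.lateral_positions
    t = motion.times
    out = np.zeros_like(motion.data)

    if spec.reverb_amplitude > 0 and motion.frame_labels is not None:
        push_idx = [i for i, l in enumerate(motion.frame_labels) if l == LABEL_PUSH]
        if not push_idx and spec.reverb_frames > 0:
            raise ParameterError("artifact spec requests reverberation frames but "
                                 "the motion field has no push-labelled frames")
        bad = list(push_idx)
        if push_idx:
            last = push_idx[-1]
            bad += [i for i in range(last + 1,
                                     min(last + 1 + spec.reverb_frames,
                                         motion.data.shape[-1]))]
        rng = np.random.default_rng(scenario.seed + 1)
        rough = rng.standard_normal(motion.data.shape[:-1] + (len(bad),))
        out[..., bad] += spec.reverb_amplitude * rough

    if spec.rigid_motion_amplitude > 0:
        drift = spec.rigid_motion_amplitude * np.sin(
            2.0 * np.pi * spec.rigid_motion_frequency * t)
        out += drift[None, :] if motion.data.ndim == 2 else drift[None, None, :]

    if spec.reflection_coefficient > 0 and spec.reflection_position is not None:
        b = spec.reflection_position
        if not (x.min() <= b <= x.max()):
            raise ParameterError("reflection boundary lies outside the lateral span")
        # mirrored pulse: total path (b − x0) + (b − x); decays with the path
        sgn = 1.0 if scenario.direction == "rightward" else -1.0
        path = sgn * ((b - scenario.origin_x) + (b - x))
        path = np.maximum(path, 1e-9)
        decay = np.ones_like(path) if scenario.decay_exponent == 0 else \
            (DECAY_REFERENCE_M / path) ** scenario.decay_exponent
        tau = t[None, :] - scenario.start_time - (path / scenario.true_sws)[:, None]
        refl = (spec.reflection_coefficient * scenario.amplitude * decay[:, None]
                * np.exp(-tau**2 / (2.0 * scenario.pulse_sigma**2)))
        out += refl if motion.data.ndim == 2 else refl[None, :, :]

    return out


def add_artifacts(motion: MotionField, spec: ArtifactSpec,
                  scenario: ShearWaveScenario) -> MotionField:
    """Superimpose acquisition artifacts on a clean motion field.

    Output equals input plus :func:`artifact_field` exactly; with all
    artifact amplitudes zero the input is returned bit-exactly.
    """
    out = motion.copy_with(data=motion.data + artifact_field(motion, spec,
                                                             scenario))
    out.log("add_artifacts", reverb_frames=spec.reverb_frames,
            reverb_amplitude=spec.reverb_amplitude,
            rigid_motion_amplitude=spec.rigid_motion_amplitude,
            reflection_coefficient=spec.reflection_coefficient)
    return out


def _bandlimited_speckle(rng: np.random.Generator, n_axial: int, n_lateral: int,
                         cutoff_fraction: float) -> np.ndarray:
    """Complex circular-Gaussian speckle columns, band-limited along fast time.

    cutoff_fraction is the (two-sided) retained band as a fraction of the
    fast-time sampling rate; the FFT brick mask makes the realisation
    exactly band-limited and periodic, so FFT resampling of it is exact.
    """
    white = (rng.standard_normal((n_axial, n_lateral))
             + 1j * rng.standard_normal((n_axial, n_lateral)))
    f = np.fft.fftfreq(n_axial)
    mask = (np.abs(f) <= cutoff_fraction / 2.0)[:, None]
    spec = np.fft.fft(white, axis=0) * mask
    col = np.fft.ifft(spec, axis=0)
    # normalise to unit mean power
    col /= np.sqrt(np.mean(np.abs(col) ** 2))
    return col


def render_iq_ensemble(motion: MotionField, speckle: SpeckleConfig, fc: float,
                       sound_speed: float,
                       rf_center_frequency: Optional[float] = None,
                       ) -> IQEnsemble:
    """Render a speckle IQ ensemble whose phase encodes the motion field.

    Frame i at lateral position x is the reference speckle column multiplied
    by exp(+i·4π·f·u(x, tᵢ)/c) with f the true RF centre frequency
    (``rf_center_frequency`` if given, else ``fc``). When the two differ,
    the columns also carry the residual-carrier phase ramp along fast time
    that a frequency-tracking estimator can exploit. Displacements at or
    beyond the quarter-wavelength alias bound c/(8·fc) set
    ``alias_warning`` on the output rather than raising.
    """
    if fc <= 0 or sound_speed <= 0:
        raise ParameterError("fc and sound_speed must be positive")
    if motion.quantity != Q_DISPLACEMENT:
        raise ParameterError("render_iq_ensemble expects displacement input")
    u = motion.data
    if u.ndim == 3:
        # collapse to lateral x time; the phase model has no axial structure
        u = u.mean(axis=0)
    rng = np.random.default_rng(speckle.seed)
    # fast-time sampling rate implied by the axial interval (two-way path)
    dt_fast = 2.0 * speckle.axial_interval / sound_speed
    fs_fast = 1.0 / dt_fast
    cutoff = speckle.fractional_bandwidth * fc / fs_fast  # fraction of fs
    ref = _bandlimited_speckle(rng, speckle.axial_samples,
                               len(motion.lateral_positions), cutoff)
    f_true = fc if rf_center_frequency is None else rf_center_frequency
    if rf_center_frequency is not None:
        t_fast = np.arange(speckle.axial_samples) * dt_fast
        ref = ref * np.exp(1j * 2.0 * np.pi * (rf_center_frequency - fc)
                           * t_fast)[:, None]

    phase = 4.0 * np.pi * f_true * u / sound_speed  # (lateral, time)
    data = ref[:, :, None] * np.exp(1j * phase)[None, :, :]

    # phase wraps at |4π·fc·u/c| = π, i.e. |u| = c/(4·fc) = λ/4
    alias_bound = sound_speed / (4.0 * fc)
    alias = bool(np.any(np.abs(u) >= alias_bound))
    if alias:
        warnings.warn("displacement reaches the quarter-wavelength alias bound "
                      f"c/(4 fc) = {alias_bound:.3e} m; phase-shift estimates "
                      "will wrap", stacklevel=2)

    if np.isfinite(speckle.snr_db):
        npow = 10.0 ** (-speckle.snr_db / 10.0)
        noise = np.sqrt(npow / 2.0) * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape))
        data = data + noise

    iq = IQEnsemble(
        data=data, fc=fc, sound_speed=sound_speed,
        axial_interval=speckle.axial_interval,
        lateral_positions=motion.lateral_positions.copy(),
        frame_times=motion.times.copy(),
        frame_labels=(motion.frame_labels.copy() if motion.frame_labels is not None
                      else np.array([LABEL_TRACK] * len(motion.times), dtype=object)),
        alias_warning=alias,
        provenance=list(motion.provenance),
    )
    iq.provenance.append({"op": "render_iq_ensemble",
                          "config": {"fc_hz": fc, "snr_db": speckle.snr_db,
                                     "seed": speckle.seed,
                                     "rf_center_frequency": rf_center_frequency}})
    return iq


def render_shifted_rf_ensemble(motion: MotionField, fs: float, fc: float,
                               sound_speed: float, n_samples: int = 512,
                               fractional_bandwidth: float = 0.6,
                               seed: int = 0) -> RFEnsemble:
    """RF ensemble built by sub-sample shifting a band-limited RF trace.

    Unlike the pure-phase IQ model this moves the whole speckle pattern:
    a displacement u delays the echo by 2u/c, realised by cubic-spline
    resampling of an upsampled master trace. Used to exercise
    correlation-based tracking with realistic (non-ideal) interpolation
    error.
    """
    if motion.quantity != Q_DISPLACEMENT:
        raise ParameterError("render_shifted_rf_ensemble expects displacement")
    u = motion.data
    if u.ndim == 3:
        u = u.mean(axis=0)
    rng = np.random.default_rng(seed)
    n_lat, n_t = u.shape
    t_fast = np.arange(n_samples) / fs
    # band-limited RF speckle: noise convolved into the transducer band
    half_band = fractional_bandwidth * fc / 2.0
    master = np.zeros((n_samples, n_lat))
    for j in range(n_lat):
        white = rng.standard_normal(n_samples)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n_samples, 1.0 / fs)
        spec[(f < fc - half_band) | (f > fc + half_band)] = 0.0
        master[:, j] = np.fft.irfft(spec, n_samples)
    data = np.empty((n_samples, n_lat, n_t))
    for j in range(n_lat):
        cs = CubicSpline(t_fast, master[:, j])
        for i in range(n_t):
            delay = 2.0 * u[j, i] / sound_speed
            shifted_t = np.clip(t_fast - delay, t_fast[0], t_fast[-1])
            data[:, j, i] = cs(shifted_t)
    return RFEnsemble(
        data=data, fs=fs, fc=fc, sound_speed=sound_speed,
        lateral_positions=motion.lateral_positions.copy(),
        frame_times=motion.times.copy(),
        frame_labels=(motion.frame_labels.copy() if motion.frame_labels is not None
                      else np.array([LABEL_TRACK] * n_t, dtype=object)),
        provenance=list(motion.provenance),
    )


def simulate_point_target_pair(offset: float, psf_lateral_sigma: float = 0.5e-3,
                               psf_axial_sigma: float = 0.3e-3,
                               lateral_span: float = 20.0e-3,
                               lateral_interval: float = 0.3e-3,
                               axial_span: float = 10.0e-3,
                               axial_interval: float = 0.1e-3,
                               speckle_noise: float = 0.0, seed: int = 0):
    """Two point-target envelope images identical up to a lateral shift.

    The wire target is imaged at lateral −offset/2 in the first image and
    +offset/2 in the second (axially centred), blurred by a Gaussian point
    spread function. Optional multiplicative speckle-like noise (fractional
    std ``speckle_noise``) is drawn independently per image.
    """
    from .calibration import PointTargetImage

    if psf_lateral_sigma <= 0 or psf_axial_sigma <= 0:
        raise ParameterError("PSF sigmas must be positive")
    lat = np.arange(-lateral_span / 2, lateral_span / 2 + lateral_interval / 2,
                    lateral_interval)
    ax = np.arange(0.0, axial_span + axial_interval / 2, axial_interval)
    if abs(offset) / 2 + 3 * psf_lateral_sigma > lat[-1]:
        raise ParameterError("grid too small: target (with PSF support) falls "
                             "outside the lateral span")
    z0 = axial_span / 2.0
    rng = np.random.default_rng(seed)

    def blob(x0):
        g_lat = np.exp(-(lat - x0) ** 2 / (2 * psf_lateral_sigma**2))
        g_ax = np.exp(-(ax - z0) ** 2 / (2 * psf_axial_sigma**2))
        img = g_ax[:, None] * g_lat[None, :]
        if speckle_noise > 0:
            img = img * (1.0 + speckle_noise * rng.standard_normal(img.shape))
            img = np.clip(img, 0.0, None)
        return PointTargetImage(envelope=img, lateral_coords=lat.copy(),
                                axial_coords=ax.copy())

    return blob(-offset / 2.0), blob(+offset / 2.0)
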