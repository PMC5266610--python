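"""Pure derivations of SWEI acquisition quantities and material relations.

These are the closed-form relations a sequence designer works with: push
duration from cycle count, PRF from PRI, F-number from the focal geometry,
depth of field 8F²λ and excitation beamwidth Fλ, the IQ axial sampling
interval, the shear-wave-speed/shear-modulus relation v = sqrt(μ/ρ), and the
radiation force density f = 2αI/c. Everything is SI in and SI out,
deterministic, and side-effect free.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math

from .errors import ParameterError


def _require_positive(**kwargs) -> None:
    bad = [k for k, v in kwargs.items() if not (v > 0)]
    if bad:
        raise ParameterError("parameters must be positive: " + ", ".join(bad))


def _require_nonnegative(**kwargs) -> None:
    bad = [k for k, v in kwargs.items() if not (v >= 0)]
    if bad:
        raise ParameterError("parameters must be non-negative: " + ", ".join(bad))


@dataclass(frozen=True)
class MediumSpec:
    """Acoustic/elastic description of the propagation medium.

    sound_speed in m/s, density in kg/m³, attenuation in Np/m,
    shear_modulus (ground truth, optional) in Pa.
    """

    sound_speed: float = 1540.0
    density: float = 1000.0
    attenuation: float = 0.0
    shear_modulus: Optional[float] = None

    def __post_init__(self):
        _require_positive(sound_speed=self.sound_speed, density=self.density)
        _require_nonnegative(attenuation=self.attenuation)
        if self.shear_modulus is not None:
            _require_nonnegative(shear_modulus=self.shear_modulus)

    @property
    def sws(self) -> Optional[float]:
        """Ground-truth shear wave speed, if shear_modulus is set."""
        if self.shear_modulus is None:
            return None
        return sws_from_shear_modulus(self.shear_modulus, self.density)


@dataclass(frozen=True)
class PushConfig:
    """Acoustic radiation force excitation: frequency (Hz), cycle count,
    focal depth z (m), active aperture D (m), optional focal intensity (W/m²)."""

    frequency: float
    cycles: int
    focal_depth: float
    active_aperture: float
    intensity: Optional[float] = None

    def __post_init__(self):
        _require_positive(frequency=self.frequency, focal_depth=self.focal_depth,
                          active_aperture=self.active_aperture)
        _require_nonnegative(cycles=self.cycles)
        if self.intensity is not None:
            _require_nonnegative(intensity=self.intensity)

    @property
    def duration(self) -> float:
        return push_duration(self.cycles, self.frequency)

    @property
    def f_number(self) -> float:
        return f_number(self.focal_depth, self.active_aperture)


@dataclass(frozen=True)
class TrackConfig:
    """Tracking/demodulation configuration.

    frame_schedule is (n_reference, n_push, n_track) frame counts;
    axial_interval_fraction is the IQ axial sampling interval as a fraction
    of the centre wavelength (0.25 on the reference scanner).
    """

    frequency: float
    pri: float
    frame_schedule: tuple = (4, 3, 25)
    axial_interval_fraction: float = 0.25
    channel_fs: Optional[float] = None

    def __post_init__(self):
        _require_positive(frequency=self.frequency, pri=self.pri,
                          axial_interval_fraction=self.axial_interval_fraction)
        if len(self.frame_schedule) != 3 or any(n < 0 for n in self.frame_schedule):
            raise ParameterError("frame_schedule must be 3 non-negative counts "
                                 "(reference, push, track)")
        if self.channel_fs is not None:
            _require_positive(channel_fs=self.channel_fs)

    @property
    def prf(self) -> float:
        return prf_from_pri(self.pri)

    def axial_interval(self, sound_speed: float) -> float:
        return axial_sample_interval(self.axial_interval_fraction,
                                     sound_speed, self.frequency)


@dataclass(frozen=True)
class FocalGeometry:
    """Derived focal beam geometry: F-number, wavelength λ, axial depth of
    field 8F²λ and lateral beamwidth Fλ (all metres except F)."""

    f_number: float
    wavelength: float
    dof: float
    beamwidth: float

    def __post_init__(self):
        _require_positive(f_number=self.f_number, wavelength=self.wavelength)
        if not math.isclose(self.dof, 8.0 * self.f_number**2 * self.wavelength,
                            rel_tol=1e-9):
            raise ParameterError("dof must equal 8·F²·λ")
        if not math.isclose(self.beamwidth, self.f_number * self.wavelength,
                            rel_tol=1e-9):
            raise ParameterError("beamwidth must equal F·λ")


def push_duration(cycles: float, frequency: float) -> float:
    """Duration T (s) of a push of `cycles` waveform cycles at `frequency` (Hz)."""
    _require_positive(frequency=frequency)
    _require_nonnegative(cycles=cycles)
    return cycles / frequency


def prf_from_pri(pri: float) -> float:
    """Pulse repetition frequency (Hz) from the pulse repetition interval (s)."""
    _require_positive(pri=pri)
    return 1.0 / pri


def f_number(focal_depth: float, aperture: float) -> float:
    """Transmit F-number F = z/D."""
    _require_positive(focal_depth=focal_depth, aperture=aperture)
    return focal_depth / aperture


def nominal_f_number_label(f: float) -> str:
    """Scanner-style label rounded to one decimal, e.g. 1.54 -> 'F/1.5'."""
    _require_positive(f_number=f)
    return f"F/{f:.1f}".rstrip("0").rstrip(".")


def focal_geometry(f_number: float, sound_speed: float,
                   frequency: float) -> FocalGeometry:
    """Wavelength, depth of field 8F²λ, and beamwidth Fλ for a focused beam."""
    _require_positive(f_number=f_number, sound_speed=sound_speed,
                      frequency=frequency)
    wavelength = sound_speed / frequency
    return FocalGeometry(f_number=f_number, wavelength=wavelength,
                         dof=8.0 * f_number**2 * wavelength,
                         beamwidth=f_number * wavelength)


def axial_sample_interval(fraction: float, sound_speed: float,
                          frequency: float) -> float:
    """IQ axial sampling interval (m): fraction of the centre wavelength."""
    _require_positive(fraction=fraction, sound_speed=sound_speed,
                      frequency=frequency)
    return fraction * sound_speed / frequency


def sws_from_shear_modulus(mu: float, rho: float = 1000.0) -> float:
    """Shear wave speed (m/s) in a linear elastic medium: sqrt(μ/ρ).

    With ρ = 1000 kg/m³ (soft tissue), the speed in m/s equals the square
    root of the shear modulus expressed in kPa.
    """
    _require_positive(rho=rho)
    _require_nonnegative(mu=mu)
    return math.sqrt(mu / rho)


def shear_modulus_from_sws(sws: float, rho: float = 1000.0) -> float:
    """Inverse relation: μ = ρ·v² (Pa)."""
    _require_positive(rho=rho)
    _require_nonnegative(sws=sws)
    return rho * sws**2


def force_density(attenuation: float, intensity: float,
                  sound_speed: float) -> float:
    """Radiation force density f = 2αI/c (N/m³)."""
    _require_positive(sound_speed=sound_speed)
    _require_nonnegative(attenuation=attenuation, intensity=intensity)
    return 2.0 * attenuation * intensity / sound_speed


def mechanical_impulse(attenuation: float, intensity: float, sound_speed: float,
                       cycles: float, frequency: float) -> float:
    """Impulse density f·T delivered by a push of `cycles` at `frequency`.

    Tissue displacement magnitude is proportional to this product, so at
    fixed force density doubling the cycle count doubles the impulse.
    """
    return (force_density(attenuation, intensity, sound_speed)
            * push_duration(cycles, frequency))


def max_trackable_sws(pri: float, lateral_span: float) -> float:
    """Heuristic Nyquist-style bound on the trackable shear wave speed.

    Package convention (not a literature formula): the speed at which a
    wavefront crosses the full lateral tracking span in two frames,
    span / (2·PRI). Faster waves are sampled fewer than twice while inside
    the field of view and cannot be reliably tracked.
    """
    _require_positive(pri=pri, lateral_span=lateral_span)
    return lateral_span / (2.0 * pri)


def derived_table(medium: MediumSpec, push: PushConfig, track: TrackConfig,
                  lateral_span: Optional[float] = None) -> dict:
    """All derived sequence quantities in one dict (SI units); used by the CLI."""
    geom = focal_geometry(push.f_number, medium.sound_speed, push.frequency)
    out = {
        "push_duration_s": push.duration,
        "push_f_number": push.f_number,
        "prf_hz": track.prf,
        "push_wavelength_m": geom.wavelength,
        "dof_m": geom.dof,
        "beamwidth_m": geom.beamwidth,
        "axial_interval_m": track.axial_interval(medium.sound_speed),
    }
    if push.intensity is not None:
        out["force_density_n_per_m3"] = force_density(
            medium.attenuation, push.intensity, medium.sound_speed)
    if medium.shear_modulus is not None:
        out["true_sws_mps"] = medium.sws
    if lateral_span is not None:
        out["max_trackable_sws_mps"] = max_trackable_sws(track.pri, lateral_span)
    return out
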