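"""Core in-memory containers shared across the pipeline.

The working currency of the pipeline is :class:`MotionField` — particle
displacement or velocity as a function of (axial, lateral, slow time) —
produced from an :class:`IQEnsemble` by a motion estimator, conditioned by
the filtering stage, and consumed by the shear-wave-speed estimators via an
:class:`ArrivalTimeProfile`.

All quantities are SI (metres, seconds, hertz, pascals) internally; the CLI
renders mm/µs/kPa for humans.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError

# Frame labels used in acquisition schedules.
LABEL_REFERENCE = "reference"
LABEL_PUSH = "push"
LABEL_TRACK = "track"

# MotionField.quantity values.
Q_DISPLACEMENT = "displacement"
Q_DIFFERENTIAL = "differential_displacement"
Q_VELOCITY = "velocity"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional")
    return arr


@dataclass
class IQEnsemble:
    """Beamformed complex baseband (IQ) data cube with acquisition metadata.

    data is complex, shaped (axial sample, lateral position, frame); its
    phase encodes sub-wavelength axial motion at the demodulation frequency
    ``fc``.
    """

    data: np.ndarray
    fc: float
    sound_speed: float
    axial_interval: float
    lateral_positions: np.ndarray
    frame_times: np.ndarray
    frame_labels: np.ndarray
    alias_warning: bool = False
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or not np.iscomplexobj(self.data):
            raise ParameterError("IQEnsemble.data must be a complex 3-D array "
                                 "(axial x lateral x frame)")
        self.lateral_positions = _as_float_array(self.lateral_positions,
                                                 "lateral_positions")
        self.frame_times = _as_float_array(self.frame_times, "frame_times")
        self.frame_labels = np.asarray(self.frame_labels, dtype=object)
        if self.fc <= 0:
            raise ParameterError("fc must be positive")
        if self.sound_speed <= 0:
            raise ParameterError("sound_speed must be positive")
        if self.axial_interval <= 0:
            raise ParameterError("axial_interval must be positive")
        n_ax, n_lat, n_fr = self.data.shape
        if len(self.lateral_positions) != n_lat:
            raise ParameterError("lateral_positions length does not match data")
        if len(self.frame_times) != n_fr or len(self.frame_labels) != n_fr:
            raise ParameterError("frame_times/frame_labels length does not match data")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ParameterError("frame_times must be strictly increasing")
        d = np.diff(self.lateral_positions)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ParameterError("lateral_positions must be strictly monotonic")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def axial_positions(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.axial_interval

    def reference_frame_index(self) -> int:
        """Last frame labelled 'reference' before the first push frame.

        Falls back to the last reference frame anywhere, then frame 0.
        """
        labels = list(self.frame_labels)
        push = [i for i, l in enumerate(labels) if l == LABEL_PUSH]
        refs = [i for i, l in enumerate(labels) if l == LABEL_REFERENCE]
        if push and refs:
            before = [i for i in refs if i < push[0]]
            if before:
                return before[-1]
        if refs:
            return refs[-1]
        return 0


@dataclass
class RFEnsemble:
    """Real radio-frequency data cube (fast time x lateral x frame)."""

    data: np.ndarray
    fs: float
    fc: float
    sound_speed: float
    lateral_positions: np.ndarray
    frame_times: np.ndarray
    frame_labels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("RFEnsemble.data must be a real 3-D array")
        self.lateral_positions = _as_float_array(self.lateral_positions,
                                                 "lateral_positions")
        self.frame_times = _as_float_array(self.frame_times, "frame_times")
        self.frame_labels = np.asarray(self.frame_labels, dtype=object)
        if self.fs <= 0 or self.fc <= 0 or self.sound_speed <= 0:
            raise ParameterError("fs, fc, sound_speed must be positive")


@dataclass
class MotionField:
    """Displacement or velocity vs (axial,) lateral and slow time.

    data is either 3-D (axial, lateral, time) or, after axial projection,
    2-D (lateral, time). ``quantity`` is one of 'displacement',
    'differential_displacement' (per-frame increments from a progressive
    reference) or 'velocity'.
    """

    data: np.ndarray
    quantity: str
    times: np.ndarray
    lateral_positions: np.ndarray
    axial_positions: Optional[np.ndarray] = None
    frame_labels: Optional[np.ndarray] = None
    interpolated_mask: Optional[np.ndarray] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ParameterError("MotionField.data must be 2-D or 3-D")
        if self.quantity not in (Q_DISPLACEMENT, Q_DIFFERENTIAL, Q_VELOCITY):
            raise ParameterError(f"unknown quantity {self.quantity!r}")
        self.times = _as_float_array(self.times, "times")
        self.lateral_positions = _as_float_array(self.lateral_positions,
                                                 "lateral_positions")
        n_t = self.data.shape[-1]
        n_lat = self.data.shape[-2]
        if len(self.times) != n_t:
            raise ParameterError("times length does not match data")
        if len(self.lateral_positions) != n_lat:
            raise ParameterError("lateral_positions length does not match data")
        if self.data.ndim == 3:
            if self.axial_positions is None:
                self.axial_positions = np.arange(self.data.shape[0], dtype=float)
            else:
                self.axial_positions = _as_float_array(self.axial_positions,
                                                       "axial_positions")
                if len(self.axial_positions) != self.data.shape[0]:
                    raise ParameterError("axial_positions length does not match data")
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(n_t, dtype=bool)
        else:
            self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
            if len(self.interpolated_mask) != n_t:
                raise ParameterError("interpolated_mask length does not match times")
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels, dtype=object)
            if len(self.frame_labels) != n_t:
                raise ParameterError("frame_labels length does not match times")

    @property
    def is_projected(self) -> bool:
        return self.data.ndim == 2

    @property
    def dt(self) -> float:
        """Uniform slow-time sampling interval; raises if non-uniform."""
        d = np.diff(self.times)
        if len(d) == 0:
            raise ParameterError("need at least two frames")
        if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
            from .errors import StateError
            raise StateError("slow-time sampling is not uniform; run "
                             "reverberation-frame repair first")
        return float(d[0])

    def copy_with(self, **kw) -> "MotionField":
        base = dict(
            data=self.data.copy(), quantity=self.quantity,
            times=self.times.copy(),
            lateral_positions=self.lateral_positions.copy(),
            axial_positions=None if self.axial_positions is None
            else self.axial_positions.copy(),
            frame_labels=None if self.frame_labels is None
            else self.frame_labels.copy(),
            interpolated_mask=self.interpolated_mask.copy(),
            provenance=list(self.provenance),
        )
        base.update(kw)
        return MotionField(**base)

    def log(self, op: str, **config) -> None:
        """Append a provenance record for an applied operation."""
        self.provenance.append({"op": op, "config": config})


@dataclass
class ArrivalTimeProfile:
    """Shear-wave arrival time vs lateral position — input to the TOF fits."""

    lateral_positions: np.ndarray
    arrival_times: np.ndarray
    feature: str
    quality: Optional[np.ndarray] = None

    def __post_init__(self):
        self.lateral_positions = _as_float_array(self.lateral_positions,
                                                 "lateral_positions")
        self.arrival_times = _as_float_array(self.arrival_times, "arrival_times")
        if len(self.lateral_positions) != len(self.arrival_times):
            raise ParameterError("positions/times length mismatch")
        if np.any(np.diff(self.lateral_positions) <= 0):
            raise ParameterError("lateral_positions must be strictly increasing")
        if self.quality is not None:
            self.quality = _as_float_array(self.quality, "quality")
            if len(self.quality) != len(self.arrival_times):
                raise ParameterError("quality length mismatch")

    def __len__(self) -> int:
        return len(self.arrival_times)


@dataclass
class SWSEstimate:
    """Group shear wave speed with fit diagnostics."""

    sws: float
    intercept: float
    method: str
    success: bool = True
    message: str = ""
    r_squared: Optional[float] = None
    ci95: Optional[tuple] = None
    inlier_fraction: Optional[float] = None
    roi: Optional[object] = None
    n_points: Optional[int] = None
    quality: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "sws_mps": self.sws, "intercept_s": self.intercept,
            "method": self.method, "success": self.success,
            "message": self.message, "r_squared": self.r_squared,
            "ci95_mps": list(self.ci95) if self.ci95 is not None else None,
            "inlier_fraction": self.inlier_fraction,
            "n_points": self.n_points, "quality": self.quality,
        }
        if self.roi is not None:
            d["roi"] = getattr(self.roi, "__dict__", str(self.roi))
        return d
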