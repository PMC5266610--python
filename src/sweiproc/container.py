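"""HDF5 interchange container for IQ ensembles, motion fields and results.

Layout (schema version 1):

    /iq            complex dataset [axial x lateral x frame]
                   attrs: fc_hz, c_mps, axial_interval_m, pri_s
    /motion        float dataset [axial x lateral x time] or [lateral x time]
                   attrs: quantity, units; dataset interpolated_mask
    /meta          lateral_positions_m, frame_times_s, frame_labels,
                   axial_positions_m (optional), provenance (JSON string,
                   append-only), schema_version

Either /iq or /motion (or both) may be present. Reading a container
written by this module reproduces all arrays bit-exactly. Validation
errors list every missing field at once.
"""
from __future__ import annotations

import json
from typing import Optional, Union

import h5py
import numpy as np

from .datatypes import IQEnsemble, MotionField
from .errors import ValidationError

SCHEMA_VERSION = 1

_IQ_ATTRS = ("fc_hz", "c_mps", "axial_interval_m")


def _units_for(quantity: str) -> str:
    return {"displacement": "m", "differential_displacement": "m",
            "velocity": "m/s"}[quantity]


def write_container(path: str, iq: Optional[IQEnsemble] = None,
                    motion: Optional[MotionField] = None) -> None:
    """Write an IQ ensemble and/or motion field to an HDF5 container."""
    if iq is None and motion is None:
        raise ValidationError("nothing to write: provide iq and/or motion")
    src = iq if iq is not None else motion
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        if iq is not None:
            g = f.create_group("iq")
            g.create_dataset("data", data=iq.data)
            g.attrs["fc_hz"] = iq.fc
            g.attrs["c_mps"] = iq.sound_speed
            g.attrs["axial_interval_m"] = iq.axial_interval
            g.attrs["alias_warning"] = iq.alias_warning
            if len(iq.frame_times) > 1:
                g.attrs["pri_s"] = float(np.median(np.diff(iq.frame_times)))
        if motion is not None:
            g = f.create_group("motion")
            g.create_dataset("data", data=motion.data)
            g.attrs["quantity"] = motion.quantity
            g.attrs["units"] = _units_for(motion.quantity)
            g.create_dataset("interpolated_mask", data=motion.interpolated_mask)
            if motion.axial_positions is not None and motion.data.ndim == 3:
                meta.create_dataset("axial_positions_m",
                                    data=motion.axial_positions)
        if motion is not None and iq is None:
            lat, times, labels = (motion.lateral_positions, motion.times,
                                  motion.frame_labels)
        else:
            lat, times, labels = (iq.lateral_positions, iq.frame_times,
                                  iq.frame_labels)
        meta.create_dataset("lateral_positions_m", data=lat)
        meta.create_dataset("frame_times_s", data=times)
        if labels is not None:
            meta.create_dataset("frame_labels",
                                data=np.array([str(l) for l in labels],
                                              dtype=h5py.string_dtype()))
        meta.create_dataset("provenance",
                            data=json.dumps(list(src.provenance)))
        if motion is not None and iq is not None:
            f["motion"].create_dataset(
                "times_s", data=motion.times)
            f["motion"].create_dataset(
                "lateral_positions_m", data=motion.lateral_positions)


def _missing(group, names, kind: str, found: list) -> None:
    for name in names:
        if name not in group:
            found.append(f"{kind} {name}")


def read_container(path: str) -> dict:
    """Read a container; returns {'iq': IQEnsemble|None,
    'motion': MotionField|None, 'provenance': list}."""
    with h5py.File(path, "r") as f:
        problems = []
        if "meta" not in f:
            raise ValidationError("missing group: meta")
        meta = f["meta"]
        if "schema_version" not in meta.attrs:
            raise ValidationError("missing attr: meta/schema_version")
        version = int(meta.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unknown schema_version {version} "
                                  f"(supported: {SCHEMA_VERSION})")
        _missing(meta, ("lateral_positions_m", "frame_times_s"), "meta dataset",
                 problems)
        if "iq" in f:
            for a in _IQ_ATTRS:
                if a not in f["iq"].attrs:
                    problems.append(f"iq attr {a}")
            _missing(f["iq"], ("data",), "iq dataset", problems)
        if "motion" in f:
            for a in ("quantity", "units"):
                if a not in f["motion"].attrs:
                    problems.append(f"motion attr {a}")
            _missing(f["motion"], ("data",), "motion dataset", problems)
        if problems:
            raise ValidationError("container validation failed; missing: "
                                  + ", ".join(problems))

        lat = meta["lateral_positions_m"][:]
        times = meta["frame_times_s"][:]
        labels = (np.array([s.decode() if isinstance(s, bytes) else str(s)
                            for s in meta["frame_labels"][:]], dtype=object)
                  if "frame_labels" in meta else None)
        provenance = json.loads(meta["provenance"][()]) \
            if "provenance" in meta else []

        iq = None
        if "iq" in f:
            g = f["iq"]
            iq = IQEnsemble(
                data=g["data"][:], fc=float(g.attrs["fc_hz"]),
                sound_speed=float(g.attrs["c_mps"]),
                axial_interval=float(g.attrs["axial_interval_m"]),
                lateral_positions=lat, frame_times=times,
                frame_labels=(labels if labels is not None
                              else np.array(["track"] * len(times),
                                            dtype=object)),
                alias_warning=bool(g.attrs.get("alias_warning", False)),
                provenance=list(provenance))
        mo = None
        if "motion" in f:
            g = f["motion"]
            m_times = g["times_s"][:] if "times_s" in g else times
            m_lat = g["lateral_positions_m"][:] \
                if "lateral_positions_m" in g else lat
            data = g["data"][:]
            mo = MotionField(
                data=data, quantity=str(g.attrs["quantity"]),
                times=m_times, lateral_positions=m_lat,
                axial_positions=(meta["axial_positions_m"][:]
                                 if "axial_positions_m" in meta
                                 and data.ndim == 3 else None),
                frame_labels=(labels if labels is not None
                              and len(labels) == len(m_times) else None),
                interpolated_mask=(g["interpolated_mask"][:]
                                   if "interpolated_mask" in g else None),
                provenance=list(provenance))
    return {"iq": iq, "motion": mo, "provenance": provenance}


def container_info(path: str) -> dict:
    """Shapes, schema and provenance chain of a container (for the CLI)."""
    with h5py.File(path, "r") as f:
        info = {"schema_version": int(f["meta"].attrs.get("schema_version", -1))
                if "meta" in f else None, "groups": {}}
        for name in ("iq", "motion"):
            if name in f:
                info["groups"][name] = {
                    "shape": list(f[name]["data"].shape),
                    "dtype": str(f[name]["data"].dtype),
                    "attrs": {k: (v.item() if hasattr(v, "item") else str(v))
                              for k, v in f[name].attrs.items()},
                }
        if "meta" in f and "provenance" in f["meta"]:
            info["provenance"] = json.loads(f["meta"]["provenance"][()])
    return info
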