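"""File round-tripping: waveform/trace CSV, gate tables, map containers.

Waveforms travel as two-column headerless CSV (time_s, volts) with a
sidecar JSON metadata record; voltage/current traces as three-column CSV
(time_s, volts, amperes); PCD traces as two-column CSV.  Floats are
written with 17 significant digits so every round trip is bit-exact.
Field and dose maps persist in HDF5 with one dataset per harmonic plus
grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .bioheat import ThermalDoseMap
from .field import FieldMap, Grid
from .gates import GATE_NAMES, GateSchedule
from .pcd import PCDRecording
from .power import VITrace
from .waveforms import SwitchedWaveform

__all__ = [
    "write_waveform", "read_waveform",
    "write_vi_trace", "read_vi_trace",
    "write_pcd_trace", "read_pcd_trace",
    "write_gate_table",
    "save_field_map", "load_field_map",
    "save_dose_map", "load_dose_map",
    "write_report",
]

_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_waveform(path, waveform: SwitchedWaveform) -> None:
    path = Path(path)
    data = np.column_stack((waveform.times, waveform.samples_volts))
    np.savetxt(path, data, fmt=_FMT, delimiter=",")
    meta = {
        "scheme": waveform.scheme,
        "centre_frequency": waveform.centre_frequency,
        "sample_rate": waveform.sample_rate,
        "rail_step": waveform.rail_step,
        **{k: v for k, v in waveform.metadata.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_waveform(path) -> SwitchedWaveform:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    volts = data[:, 1]
    scheme = meta["scheme"]
    rail = float(meta["rail_step"])
    if scheme == "sine":
        levels = volts / rail
    else:
        levels = np.rint(volts / rail).astype(np.int64)
        if np.max(np.abs(levels * rail - volts)) > 1e-9 * max(rail, 1.0):
            raise ValueError("volts column is not an exact multiple of rail_step")
    return SwitchedWaveform(
        sample_rate=float(meta["sample_rate"]),
        levels=levels,
        rail_step=rail,
        centre_frequency=float(meta["centre_frequency"]),
        scheme=scheme,
        metadata={k: v for k, v in meta.items()
                  if k not in ("scheme", "centre_frequency", "sample_rate",
                               "rail_step")},
    )


def write_vi_trace(path, trace: VITrace) -> None:
    data = np.column_stack((trace.times, trace.voltage, trace.current))
    np.savetxt(path, data, fmt=_FMT, delimiter=",")


def read_vi_trace(path) -> VITrace:
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[1] != 3:
        raise ValueError("VI trace CSV must have columns time_s,volts,amperes")
    t = data[:, 0]
    return VITrace(sample_interval=float(t[1] - t[0]),
                   voltage=data[:, 1], current=data[:, 2])


def write_pcd_trace(path, recording: PCDRecording) -> None:
    t = np.arange(len(recording.trace)) / recording.sample_rate
    np.savetxt(path, np.column_stack((t, recording.trace)),
               fmt=_FMT, delimiter=",")


def read_pcd_trace(path, **trigger_kwargs) -> PCDRecording:
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[1] != 2:
        raise ValueError("PCD trace CSV must have columns time_s,volts")
    t = data[:, 0]
    return PCDRecording(sample_rate=1.0 / float(t[1] - t[0]),
                        trace=data[:, 1], **trigger_kwargs)


def write_gate_table(path, schedule: GateSchedule) -> None:
    """One row per sample, six 0/1 electrical-level columns, fixed order."""
    table = schedule.to_table()
    header = ",".join(GATE_NAMES)
    np.savetxt(path, table, fmt="%d", delimiter=",", header=header, comments="")


def _write_grid(group, grid: Grid) -> None:
    group.create_dataset("r", data=grid.r)
    group.create_dataset("z", data=grid.z)


def _read_grid(group) -> Grid:
    return Grid(r=group["r"][:], z=group["z"][:])


def save_field_map(path, fmap: FieldMap) -> None:
    with h5py.File(path, "w") as fh:
        _write_grid(fh.create_group("grid"), fmap.grid)
        g = fh.create_group("pressure_pa")
        for h, p in fmap.pressures.items():
            g.create_dataset(f"h{h}", data=p)
        fh.attrs["fundamental_frequency"] = fmap.fundamental_frequency
        for k, v in fmap.metadata.items():
            fh.attrs[k] = v


def load_field_map(path) -> FieldMap:
    with h5py.File(path, "r") as fh:
        grid = _read_grid(fh["grid"])
        pressures = {int(name[1:]): fh["pressure_pa"][name][:]
                     for name in fh["pressure_pa"]}
        meta = dict(fh.attrs)
        f0 = float(meta.pop("fundamental_frequency"))
    return FieldMap(grid=grid, pressures=pressures,
                    fundamental_frequency=f0, metadata=meta)


def save_dose_map(path, dose: ThermalDoseMap) -> None:
    with h5py.File(path, "w") as fh:
        _write_grid(fh.create_group("grid"), dose.grid)
        fh.create_dataset("cem43_min", data=dose.cem43_min)
        fh.attrs["threshold_min"] = dose.threshold_min
        for k, v in dose.metadata.items():
            fh.attrs[k] = v


def load_dose_map(path) -> ThermalDoseMap:
    with h5py.File(path, "r") as fh:
        grid = _read_grid(fh["grid"])
        cem = fh["cem43_min"][:]
        meta = dict(fh.attrs)
        thr = float(meta.pop("threshold_min"))
    return ThermalDoseMap(grid=grid, cem43_min=cem, threshold_min=thr,
                          metadata=meta)


def write_report(path, report_dict: dict) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=1, sort_keys=True))
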