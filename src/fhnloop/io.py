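"""Plain-text persistence: trajectories, recordings, sweep tables, sidecars.

Everything is delimited text plus a YAML sidecar (``<file>.meta.yaml``) so
runs can be inspected, diffed and re-read without special tooling.  Readers
accept the same two-column format for user-supplied data (sidecar optional).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .regimes import FrequencyCurve
from .solver import Trajectory
from .surrogate import LFPRecording

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_recording",
    "load_recording",
    "save_frequency_curve",
    "load_frequency_curve",
    "load_series",
]

_FLOAT_FMT = "%.12g"


def _pyify(obj):
    """Convert numpy scalars/arrays (recursively) into plain Python objects."""
    if isinstance(obj, dict):
        return {str(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.complexfloating)):
        return float(np.real(obj)) if np.imag(obj) == 0 else [float(np.real(obj)), float(np.imag(obj))]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar(path).write_text(yaml.safe_dump(_pyify(payload), sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar(path)
    if sc.exists():
        return yaml.safe_load(sc.read_text()) or {}
    return {}


def save_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as delimited text (t, u, v[, u2, v2]) + sidecar."""
    path = Path(path)
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter="\t",
               header="\t".join(traj.column_names()), comments="")
    _write_sidecar(path, traj.meta)
    return path


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return Trajectory(data[:, 0], data[:, 1:], meta=_read_sidecar(path))


def save_recording(rec: LFPRecording, path) -> Path:
    """Write a recording as two-column text (time_ms, voltage_mv) + sidecar."""
    path = Path(path)
    np.savetxt(path, np.column_stack([rec.times_ms, rec.voltage_mv]),
               fmt=_FLOAT_FMT, delimiter="\t", header="time_ms\tvoltage_mv",
               comments="")
    _write_sidecar(path, {
        "stim_times_ms": rec.stim_times_ms,
        "truth": rec.truth,
        "config": rec.meta,
    })
    return path


def load_recording(path) -> LFPRecording:
    """Read a two-column recording; sidecar (stim times, truth) is optional."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    side = _read_sidecar(path)
    return LFPRecording(
        data[:, 0], data[:, 1],
        np.asarray(side.get("stim_times_ms", []), dtype=float),
        truth=side.get("truth", {}),
        meta=side.get("config", {}),
    )


def save_frequency_curve(curve: FrequencyCurve, path) -> Path:
    """Write a sweep as a 4-column table + a YAML summary sidecar."""
    path = Path(path)
    lines = ["swept_value\tfrequency\tspike_count\tlabel"]
    for d, f, n, lab in zip(curve.sweep_values, curve.frequencies,
                            curve.spike_counts, curve.labels):
        lines.append(f"{d:.12g}\t{f:.12g}\t{n:d}\t{lab}")
    path.write_text("\n".join(lines) + "\n")
    _write_sidecar(path, {"meta": curve.meta, "errors": curve.errors})
    return path


def load_frequency_curve(path) -> FrequencyCurve:
    path = Path(path)
    rows = [ln.split("\t") for ln in path.read_text().splitlines()[1:] if ln]
    side = _read_sidecar(path)
    return FrequencyCurve(
        [float(r[0]) for r in rows],
        [float(r[1]) for r in rows],
        [int(r[2]) for r in rows],
        [r[3] for r in rows],
        errors={int(k): v for k, v in (side.get("errors") or {}).items()},
        meta=side.get("meta", {}),
    )


def load_series(path, delimiter: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Read a user-supplied (time, value) two-column delimited text file.

    Accepts tab/space/comma separation; a single non-numeric header line is
    skipped automatically.
    """
    path = Path(path)
    text = path.read_text().strip().splitlines()
    start = 0
    first = text[0].replace(",", " ").split()
    try:
        [float(x) for x in first[:2]]
    except ValueError:
        start = 1
    rows = []
    for ln in text[start:]:
        parts = ln.replace(",", " ").split() if delimiter is None else ln.split(delimiter)
        if len(parts) >= 2:
            rows.append((float(parts[0]), float(parts[1])))
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValueError(f"no numeric rows in {path}")
    return arr[:, 0], arr[:, 1]
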