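"""CSV / config / report readers and writers.

Conventions: frames are 0-based throughout and ``time_s = frame /
sample_rate_hz``.  Signal CSVs carry ``frame`` (or ``time_s``) and
``angle_deg`` columns; event CSVs carry ``frame, time_s, type, value,
source`` and are shared by detector output and ground-truth annotations.
Every CLI run writes a JSON manifest (command, config snapshot, input
checksums, package version, timestamp, seed) sufficient to re-run it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import DetectorConfig, GaitEvent
from .errors import InvalidInputError
from .signal_model import DgeiParams, GaitSignal

EVENT_SOURCES = ("pos_curve", "neg_curve", "state_machine", "truth")
_EVENT_COLUMNS = ["frame", "time_s", "type", "value", "source"]


def default_profile() -> tuple[DgeiParams, DetectorConfig]:
    """The shipped operating point: sleeptime 60, bar 9, 60 % threshold, q=5, w=10."""
    return DgeiParams(), DetectorConfig()


def read_signal(path, default_rate_hz: float = 60.0) -> GaitSignal:
    """Read a signal CSV, inferring the sample rate from ``time_s`` if present.

    Requires an ``angle_deg`` column plus either consecutive integer
    ``frame`` values or uniformly spaced ``time_s``; rejects non-finite
    samples with the offending row number (1-based data rows).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"signal file not found: {path}")
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise InvalidInputError(
            f"{path}: missing column 'angle_deg' (found {list(df.columns)})"
        )
    values = pd.to_numeric(df["angle_deg"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise InvalidInputError(f"{path}: non-finite angle_deg at data row {bad[0] + 1}")
    if "time_s" in df.columns:
        t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            row = int(np.flatnonzero(~np.isfinite(t))[0]) + 1
            raise InvalidInputError(f"{path}: non-finite time_s at data row {row}")
        if t.size < 2:
            rate, start = default_rate_hz, 0
        else:
            dt = np.diff(t)
            if np.any(dt <= 0):
                row = int(np.flatnonzero(dt <= 0)[0]) + 2
                raise InvalidInputError(f"{path}: time_s not increasing at data row {row}")
            med = float(np.median(dt))
            if np.any(np.abs(dt - med) > max(1e-9, 1e-4 * med)):
                row = int(np.flatnonzero(np.abs(dt - med) > max(1e-9, 1e-4 * med))[0]) + 2
                raise InvalidInputError(f"{path}: non-uniform sampling near data row {row}")
            rate = 1.0 / med
            start = int(round(t[0] * rate))
    elif "frame" in df.columns:
        frames = pd.to_numeric(df["frame"], errors="coerce").to_numpy()
        if np.any(~np.isfinite(frames)) or np.any(frames != np.round(frames)):
            raise InvalidInputError(f"{path}: 'frame' column must hold integers")
        frames = frames.astype(int)
        if frames.size > 1 and np.any(np.diff(frames) != 1):
            row = int(np.flatnonzero(np.diff(frames) != 1)[0]) + 2
            raise InvalidInputError(f"{path}: frames not consecutive at data row {row}")
        rate, start = default_rate_hz, int(frames[0]) if frames.size else 0
    else:
        raise InvalidInputError(f"{path}: need a 'frame' or 'time_s' column")
    return GaitSignal(values, sample_rate_hz=rate, start_frame=start)


def write_signal(path, signal: GaitSignal) -> None:
    df = pd.DataFrame(
        {"frame": signal.frames, "time_s": signal.times, "angle_deg": signal.values}
    )
    df.to_csv(path, index=False)


def read_events(path) -> list[GaitEvent]:
    """Read an events CSV (``frame,time_s,type,value,source``), validating rows."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"events file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "type") if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        etype = str(row.type)
        if etype not in ("HS", "TO", "WS", "WP"):
            raise InvalidInputError(f"{path}: unknown event type {etype!r} at data row {i}")
        source = str(getattr(row, "source", "state_machine"))
        if source not in EVENT_SOURCES:
            raise InvalidInputError(f"{path}: unknown source {source!r} at data row {i}")
        try:
            frame = int(row.frame)
            value = float(getattr(row, "value", 0.0))
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: malformed numeric field at data row {i}") from exc
        events.append(GaitEvent(frame, etype, value, source))
    return events


def write_events(path, events: list[GaitEvent], sample_rate_hz: float = 60.0) -> None:
    df = pd.DataFrame(
        {
            "frame": [e.frame for e in events],
            "time_s": [e.frame / sample_rate_hz for e in events],
            "type": [e.type for e in events],
            "value": [e.value for e in events],
            "source": [e.source for e in events],
        },
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_config(path) -> tuple[DgeiParams, DetectorConfig]:
    """Load a YAML/JSON config with optional ``dgei`` and ``detector`` sections."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    unknown = set(data) - {"dgei", "detector"}
    if unknown:
        raise InvalidInputError(f"{path}: unknown top-level keys {sorted(unknown)}")
    params, config = default_profile()
    try:
        if "dgei" in data:
            params = dataclasses.replace(params, **data["dgei"])
        if "detector" in data:
            config = dataclasses.replace(config, **data["detector"])
    except TypeError as exc:
        raise InvalidInputError(f"{path}: {exc}") from exc
    return params, config


def config_snapshot(params: DgeiParams, config: DetectorConfig) -> dict:
    return {"dgei": dataclasses.asdict(params), "detector": dataclasses.asdict(config)}


def write_config(path, params: DgeiParams, config: DetectorConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_snapshot(params, config), sort_keys=False))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: list[str], config: dict, inputs: list, seed=None) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "package_version": __version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def write_report(path, reports: dict) -> None:
    """Serialize per-type :class:`~dgei.metrics.EvalReport` objects to JSON."""
    payload = {k: (v.to_dict() if hasattr(v, "to_dict") else v) for k, v in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
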