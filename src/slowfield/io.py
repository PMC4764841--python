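"""Session persistence.

A session is stored as an HDF5 container (``/data`` sensors-by-samples,
``/sensors/positions``, ``/sensors/orientations``, ``/sensors/parietal_mask``;
root attributes ``rate``, ``lowpass``, ``seed``, ``schema``) plus two text
sidecars next to it: ``<stem>.events.csv`` (columns time_s, event, label)
and ``<stem>.config.json`` with the full generator configuration.
Round-trips are bitwise lossless on the data arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SessionFormatError
from .simulate import EventSchedule, MEGSession, SensorArray

SCHEMA = "slowfield-session/1"


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return (stem.parent / (stem.name + ".events.csv"),
            stem.parent / (stem.name + ".config.json"))


def write_session(path, session: MEGSession) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["rate"] = session.rate
        f.attrs["lowpass"] = session.lowpass
        f.attrs["seed"] = session.seed
        f.attrs["head_radius"] = session.sensor_array.head_radius
        f.create_dataset("data", data=session.data)
        g = f.create_group("sensors")
        g.create_dataset("positions", data=session.sensor_array.positions)
        g.create_dataset("orientations",
                         data=session.sensor_array.orientations)
        g.create_dataset("parietal_mask",
                         data=session.sensor_array.parietal_mask)
    events_path, config_path = _sidecars(path)
    rows = []
    for t, m in zip(session.schedule.instruction_times,
                    session.schedule.instruction_types):
        rows.append({"time_s": float(t), "event": f"instruction_{m}",
                     "label": m})
    for t, m in zip(session.schedule.cue_times, session.schedule.cue_types):
        rows.append({"time_s": float(t), "event": "cue", "label": m})
    pd.DataFrame(rows, columns=["time_s", "event", "label"]).sort_values(
        ["time_s", "event"]).to_csv(events_path, index=False)
    config_path.write_text(json.dumps(session.config, indent=2, default=str))
    return path


def read_session(path) -> MEGSession:
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no such session file: {path}")
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != SCHEMA:
                raise SessionFormatError(
                    f"unsupported or missing schema in {path}; "
                    f"expected {SCHEMA!r}")
            for key in ("data", "sensors/positions", "sensors/orientations",
                        "sensors/parietal_mask"):
                if key not in f:
                    raise SessionFormatError(f"{path} lacks dataset {key}")
            data = f["data"][()]
            array = SensorArray(
                positions=f["sensors/positions"][()],
                orientations=f["sensors/orientations"][()],
                parietal_mask=f["sensors/parietal_mask"][()].astype(bool),
                head_radius=float(f.attrs.get("head_radius", 0.09)),
            )
            rate = float(f.attrs["rate"])
            lowpass = float(f.attrs["lowpass"])
            seed = int(f.attrs["seed"])
    except OSError as exc:
        raise SessionFormatError(f"cannot read {path}: {exc}") from exc

    events_path, config_path = _sidecars(path)
    if events_path.exists():
        ev = pd.read_csv(events_path)
        if not ev["time_s"].is_monotonic_increasing:
            raise SessionFormatError(
                f"{events_path}: event times out of order")
        cues = ev[ev["event"] == "cue"]
        instr = ev[ev["event"].str.startswith("instruction_")]
        schedule = EventSchedule(
            cue_times=cues["time_s"].to_numpy(),
            cue_types=tuple(cues["label"]),
            instruction_times=instr["time_s"].to_numpy(),
            instruction_types=tuple(instr["label"]),
        )
    else:
        schedule = EventSchedule(np.array([]), (), np.array([]), ())
    config = json.loads(config_path.read_text()) if config_path.exists() \
        else {}
    return MEGSession(data=data, rate=rate, lowpass=lowpass,
                      schedule=schedule, sensor_array=array, seed=seed,
                      config=config)
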