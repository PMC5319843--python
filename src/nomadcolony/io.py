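"""Trajectory serialization: tidy CSV + events CSV + run manifest JSON.

Floats are written with shortest-roundtrip repr so a written trajectory
reads back bit-identically.  Files are written atomically (temp file then
rename) so a crashed run never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any

import pandas as pd

from .engine import Event, Phase, Trajectory

__all__ = ["write_trajectory", "read_trajectory"]

TRAJ_FILE = "trajectory.csv"
EVENTS_FILE = "events.csv"
MANIFEST_FILE = "manifest.json"


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _csv_text(df: pd.DataFrame) -> str:
    # repr-shortest float formatting => exact round-trip
    cols = df.columns.tolist()
    lines = [",".join(cols)]
    for row in df.itertuples(index=False):
        lines.append(",".join(
            repr(v) if isinstance(v, float) else str(v) for v in row
        ))
    return "\n".join(lines) + "\n"


def write_trajectory(
    traj: Trajectory, outdir: str | Path, manifest: dict[str, Any] | None = None
) -> dict[str, Path]:
    """Write trajectory.csv, events.csv and manifest.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    _atomic_write(outdir / TRAJ_FILE, _csv_text(traj.to_frame()))
    ev = pd.DataFrame(
        {"t": [e.time for e in traj.events],
         "event_type": [e.kind for e in traj.events]}
    )
    _atomic_write(outdir / EVENTS_FILE, _csv_text(ev))
    man = dict(manifest or {})
    man.setdefault("policy_mode", traj.policy_mode)
    man["n_samples"] = int(len(traj.times))
    man["n_events"] = len(traj.events)
    man["phases"] = [
        {"start": p.start, "end": p.end, "label": p.label} for p in traj.phases
    ]
    _atomic_write(outdir / MANIFEST_FILE, json.dumps(man, indent=2) + "\n")
    return {
        "trajectory": outdir / TRAJ_FILE,
        "events": outdir / EVENTS_FILE,
        "manifest": outdir / MANIFEST_FILE,
    }


def read_trajectory(outdir: str | Path) -> Trajectory:
    """Re-read a written trajectory with exact value round-trip."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / TRAJ_FILE, float_precision="round_trip")
    evdf = pd.read_csv(outdir / EVENTS_FILE, float_precision="round_trip")
    events = [Event(time=float(t), kind=str(k))
              for t, k in zip(evdf["t"], evdf["event_type"])]
    phases: list[Phase] = []
    try:
        man = json.loads((outdir / MANIFEST_FILE).read_text())
        phases = [Phase(start=p["start"], end=p["end"], label=p["label"])
                  for p in man.get("phases", [])]
        mode = man.get("policy_mode", "none")
    except FileNotFoundError:
        mode = "none"
    return Trajectory(
        times=df["t"].to_numpy(),
        n1=df["n1"].to_numpy(),
        n2=df["n2"].to_numpy(),
        K=df["K"].to_numpy(),
        events=events,
        phases=phases,
        policy_mode=mode,
    )
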