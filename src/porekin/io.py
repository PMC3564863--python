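"""Plain-text I/O: traces and events as TSV, models and metadata as JSON.

Traces: two-column TSV (time_s, current_pA) with a JSON sidecar carrying
voltage, sampling rate, open-pore current and seed.  Events: long-format
TSV (event_id, point_index, I_over_I0) plus a JSON index with per-event
lifetime, voltage, baseline and label.  Model JSON round-trips are
bit-exact (shortest-repr floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import RateTable
from .signals import Event, RawTrace

__all__ = [
    "write_trace", "read_trace",
    "write_events", "read_events",
    "write_rate_table",
    "write_json", "read_json",
]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_trace(trace: RawTrace, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    t = np.arange(trace.samples.size) / trace.sampling_rate_hz
    pd.DataFrame({"time_s": t, "current_pA": trace.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "voltage_mV": trace.voltage_mV,
        "sampling_rate_hz": trace.sampling_rate_hz,
        "open_pore_current_pA": trace.metadata.get("open_pore_current_pA"),
        "seed": seed,
        "metadata": {k: v for k, v in trace.metadata.items()
                     if isinstance(v, (str, int, float, bool, type(None)))},
    }
    write_json(sidecar, path.with_suffix(".json"))


def read_trace(path: str | Path) -> RawTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    side = read_json(path.with_suffix(".json"))
    meta = dict(side.get("metadata") or {})
    if side.get("open_pore_current_pA") is not None:
        meta["open_pore_current_pA"] = side["open_pore_current_pA"]
    return RawTrace(
        samples=df["current_pA"].to_numpy(),
        sampling_rate_hz=float(side["sampling_rate_hz"]),
        voltage_mV=float(side["voltage_mV"]),
        metadata=meta,
    )


def write_events(events, tsv_path: str | Path) -> None:
    tsv_path = Path(tsv_path)
    rows = []
    index = {}
    for i, ev in enumerate(events):
        eid = ev.event_id if ev.event_id is not None else i
        for k, v in enumerate(ev.values):
            rows.append((eid, k, v))
        index[str(eid)] = {
            "lifetime_s": ev.lifetime_s,
            "voltage_mV": ev.voltage_mV,
            "baseline_pA": ev.baseline_pA,
            "dt_s": ev.dt_s,
            "label": ev.class_label,
            "start_time_s": ev.start_time_s,
        }
    pd.DataFrame(rows, columns=["event_id", "point_index", "I_over_I0"]).to_csv(
        tsv_path, sep="\t", index=False)
    write_json(index, tsv_path.with_suffix(".index.json"))


def read_events(tsv_path: str | Path) -> list[Event]:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    index = read_json(Path(str(tsv_path).replace(".tsv", ".index.json"))
                      if str(tsv_path).endswith(".tsv")
                      else tsv_path.with_suffix(".index.json"))
    events = []
    for eid, grp in df.groupby("event_id", sort=True):
        info = index[str(eid)]
        events.append(Event(
            values=grp.sort_values("point_index")["I_over_I0"].to_numpy(),
            voltage_mV=float(info["voltage_mV"]),
            baseline_pA=float(info["baseline_pA"]) if info["baseline_pA"] is not None else float("nan"),
            dt_s=float(info["dt_s"]),
            class_label=info.get("label"),
            event_id=int(eid),
            start_time_s=float(info.get("start_time_s") or "nan"),
        ))
    return events


def write_rate_table(tables, path: str | Path, entry_condition: str = "all") -> None:
    """RateTable(s) as TSV: voltage_mV, from_state, to_state, entry_condition,
    N, T_s, rate_s, se."""
    if isinstance(tables, RateTable):
        tables = [tables]
    rows = []
    for t in tables:
        for i in range(t.K):
            for j in range(t.K):
                if i == j:
                    continue
                rows.append({
                    "voltage_mV": t.voltage_mV,
                    "from_state": i,
                    "to_state": j,
                    "entry_condition": entry_condition,
                    "N": t.N[i, j],
                    "T_s": t.T_s[i],
                    "rate_s": t.rate_hz[i, j],
                    "se": t.se_hz[i, j],
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
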