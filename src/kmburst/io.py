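"""Plain-text readers and writers for every pipeline artifact.

All tabular data are tidy CSV; metadata travel in JSON sidecars
(``<stem>.meta.json``).  JSON output is deterministic (sorted keys, no
timestamps) so re-running a seeded scenario reproduces files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .events import EventTrain, IdealizedTrace
from .synth import StepProtocol, SweepSet, Trace

__all__ = [
    "dump_json",
    "write_sweepset", "read_sweepset",
    "write_dose_table", "read_dose_table",
    "write_trace", "read_trace",
    "write_fit", "write_idealization", "write_event_train",
    "write_sim_trace", "write_curve",
]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def dump_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_sweepset(ss: SweepSet, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ss.data.to_csv(path, index=False)
    meta = dict(ss.meta)
    meta["protocol"] = dataclasses.asdict(ss.protocol)
    dump_json(meta, _meta_path(path))
    return path


def read_sweepset(path: Union[str, Path]) -> SweepSet:
    path = Path(path)
    data = pd.read_csv(path)
    meta = json.loads(_meta_path(path).read_text())
    proto = meta.pop("protocol")
    proto["step_levels_mV"] = tuple(proto["step_levels_mV"])
    return SweepSet(data, StepProtocol(**proto), meta)


def write_dose_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if table.attrs.get("meta"):
        dump_json(table.attrs["meta"], _meta_path(path))
    return path


def read_dose_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trace(trace: Trace, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": trace.time_ms(), "value_pA": trace.values_pA}
                 ).to_csv(path, index=False, float_format="%.6g")
    meta = {k: v for k, v in trace.meta.items()
            if k not in ("occupancy", "waveform", "spec")}
    meta["sample_interval_ms"] = trace.sample_interval_ms
    dump_json(meta, _meta_path(path))
    return path


def read_trace(path: Union[str, Path]) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    dt = meta.get("sample_interval_ms")
    if dt is None:
        t = df["time_ms"].to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    return Trace(df["value_pA"].to_numpy(float), float(dt), meta)


def write_fit(fit, path: Union[str, Path]) -> Path:
    """Serialize a fit record (HillFit / BoltzmannFit / LinearConductanceFit)."""
    return dump_json(fit, path)


def write_idealization(ideal: IdealizedTrace, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ideal.segments, columns=["start_ms", "duration_ms", "level"]
                 ).to_csv(path, index=False, float_format="%.6g")
    dump_json({"unitary_amplitude_pA": ideal.unitary_amplitude_pA,
               "baseline_pA": ideal.baseline_pA,
               "sample_interval_ms": ideal.sample_interval_ms}, _meta_path(path))
    return path


def write_event_train(train: EventTrain, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": train.event_times_s}).to_csv(path, index=False,
                                                         float_format="%.6g")
    dump_json({"duration_s": train.duration_s, "n_events": train.n_events},
              _meta_path(path))
    return path


def write_sim_trace(trace, path: Union[str, Path]) -> Path:
    """SimTrace -> CSV (time_ms, V_mV, Ca_uM, gates, per-current columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_ms": trace.t_ms, "V_mV": trace.v, "Ca_uM": trace.ca}
    for g, arr in trace.gates.items():
        cols[f"gate_{g}"] = arr
    for name, arr in trace.currents.items():
        cols[name] = arr
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
    dump_json({"params": dataclasses.asdict(trace.params),
               "config": {k: v for k, v in dataclasses.asdict(trace.config).items()
                          if k != "initial_state"},
               "modulation": dataclasses.asdict(trace.modulation)},
              _meta_path(path))
    return path


def write_curve(n: np.ndarray, o: np.ndarray, path: Union[str, Path],
                meta: dict = None) -> Path:
    """NullclineCurve / TrajectoryLoop samples as CSV (n, o)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"n": n, "o": o}).to_csv(path, index=False, float_format="%.8g")
    if meta:
        dump_json(meta, _meta_path(path))
    return path
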