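"""File formats: recordings, state sequences, epoch sets, simulation traces.

Conventions: seconds, half-open intervals [start, end), t=0 at recording
start.  Signals persist as two-column CSV (time, value) with a JSON
sidecar (same path + '.json') carrying fs, role and optional ground truth;
state sequences and epoch sets as 3-column interval files.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .intervals import StateSequence, EpochSet
from .model_core import ModelParams
from .simulator import SimTrace
from .surrogate import Recording

__all__ = ["write_recording", "read_recording", "write_state_sequence",
           "read_state_sequence", "write_epochs", "read_epochs",
           "write_trace", "read_trace"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    t = rec.t
    pd.DataFrame({"time_s": t, "value": rec.signal}).to_csv(path,
                                                            index=False)
    meta = {"fs": rec.fs, "role": rec.role}
    if rec.truth is not None:
        meta["truth_intervals"] = [list(iv) for iv in rec.truth.intervals]
        meta["truth_source"] = rec.truth.source
    if rec.truth_weights is not None:
        meta["truth_weights"] = list(rec.truth_weights)
    if rec.truth_spikes is not None:
        meta["truth_spikes"] = [float(x) for x in rec.truth_spikes]
    if rec.truth_desync is not None:
        meta["truth_desync"] = [list(iv) for iv in rec.truth_desync.intervals]
    _sidecar(path).write_text(json.dumps(meta))


def read_recording(path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"missing metadata sidecar {side} (no sampling rate)")
    meta = json.loads(side.read_text())
    if "fs" not in meta:
        raise ValueError("sidecar lacks the sampling rate 'fs'")
    if meta.get("role") not in ("vm", "lfp"):
        raise ValueError(f"unknown recording role {meta.get('role')!r}")
    df = pd.read_csv(path)
    values = df["value"].to_numpy(dtype=float)
    if np.isnan(values).any():
        first = int(np.argmax(np.isnan(values)))
        raise ValueError(f"NaN sample at index {first}")
    truth = None
    if "truth_intervals" in meta:
        truth = StateSequence([(a, b, lab) for a, b, lab
                               in meta["truth_intervals"]],
                              source=meta.get("truth_source", "model"))
    rec = Recording(signal=values, fs=float(meta["fs"]), role=meta["role"],
                    truth=truth)
    if "truth_weights" in meta:
        rec.truth_weights = tuple(meta["truth_weights"])
    if "truth_spikes" in meta:
        rec.truth_spikes = np.array(meta["truth_spikes"])
    if "truth_desync" in meta:
        rec.truth_desync = EpochSet([tuple(iv) for iv
                                     in meta["truth_desync"]],
                                    label="desynchronized")
    return rec


def write_state_sequence(seq: StateSequence, path) -> None:
    pd.DataFrame(seq.intervals,
                 columns=["start_s", "end_s", "state"]).to_csv(Path(path),
                                                               index=False)


def read_state_sequence(path, source: str = "model") -> StateSequence:
    df = pd.read_csv(Path(path))
    return StateSequence([(float(a), float(b), str(lab)) for a, b, lab in
                          zip(df["start_s"], df["end_s"], df["state"])],
                         source=source)


def write_epochs(epochs: EpochSet, path) -> None:
    rows = [(a, b, epochs.label) for a, b in epochs.intervals]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]).to_csv(
        Path(path), index=False)


def read_epochs(path) -> EpochSet:
    df = pd.read_csv(Path(path))
    label = str(df["label"].iloc[0]) if len(df) else "desynchronized"
    return EpochSet([(float(a), float(b)) for a, b
                     in zip(df["start_s"], df["end_s"])], label=label)


def write_trace(trace: SimTrace, path) -> None:
    path = Path(path)
    pd.DataFrame({"t_s": trace.t, "E": trace.E, "I": trace.I,
                  "A": trace.A}).to_csv(path, index=False)
    meta = {"dt": trace.dt, "seed": trace.seed,
            "record_every": trace.record_every,
            "params": trace.params.to_dict()}
    _sidecar(path).write_text(json.dumps(meta))


def read_trace(path) -> SimTrace:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path)
    return SimTrace(t=df["t_s"].to_numpy(), E=df["E"].to_numpy(),
                    I=df["I"].to_numpy(), A=df["A"].to_numpy(),
                    dt=meta["dt"], seed=meta["seed"],
                    params=ModelParams.from_dict(meta["params"]),
                    record_every=meta["record_every"])
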