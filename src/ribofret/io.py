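"""Reading and writing trace datasets, idealizations and analysis reports.

The normative on-disk dialect is plain text: a tab-separated trace table
(``trace_id  frame  time_s  donor  acceptor``) with a JSON metadata sidecar
named ``<stem>.meta.json`` next to it. Idealizations use the analogous table
(``trace_id  frame  fret  state_index  state_label``) with the model spec in
the sidecar. Floats are written with 6 significant digits, which makes
read/write round trips exact on files the package itself wrote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyDatasetError,
    MissingSidecarError,
    NonUniformGridError,
    TraceFormatError,
)

__all__ = [
    "TraceMeta",
    "TraceSet",
    "IdealizedSet",
    "read_traces",
    "write_traces",
    "read_idealization",
    "write_idealization",
    "write_report",
    "read_report",
]

_TRACE_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]
_IDEAL_COLUMNS = ["trace_id", "frame", "fret", "state_index", "state_label"]
_FLOAT_FMT = "%.6g"


@dataclass
class TraceMeta:
    """Acquisition metadata stored in the JSON sidecar."""

    frame_interval_s: float
    condition: str = ""
    codon: str = ""
    fluorophore_pair: str = ""
    ternary_concentration_uM: float = 0.0
    background_level: float = 0.0
    background_noise_sd: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TraceMeta":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


@dataclass
class TraceSet:
    """Per-frame donor/acceptor intensities for many molecules.

    ``frames`` is a long-format DataFrame with columns
    ``trace_id, frame, time_s, donor, acceptor``, sorted by trace then frame.
    """

    frames: pd.DataFrame
    meta: TraceMeta

    def __post_init__(self):
        missing = [c for c in _TRACE_COLUMNS if c not in self.frames.columns]
        if missing:
            raise TraceFormatError(f"trace table missing columns: {missing}")
        self.frames = self.frames[_TRACE_COLUMNS].reset_index(drop=True)
        _validate_trace_frames(self.frames, self.meta.frame_interval_s)

    @property
    def trace_ids(self) -> list:
        return list(dict.fromkeys(self.frames["trace_id"]))

    @property
    def n_traces(self) -> int:
        return self.frames["trace_id"].nunique()

    def trace(self, trace_id) -> pd.DataFrame:
        sub = self.frames[self.frames["trace_id"] == trace_id]
        if sub.empty:
            raise KeyError(trace_id)
        return sub.reset_index(drop=True)

    def iter_traces(self):
        for tid, sub in self.frames.groupby("trace_id", sort=False):
            yield tid, sub.reset_index(drop=True)

    def subset(self, trace_ids) -> "TraceSet":
        keep = set(trace_ids)
        sub = self.frames[self.frames["trace_id"].isin(keep)].reset_index(drop=True)
        return TraceSet(frames=sub, meta=self.meta)


@dataclass
class IdealizedSet:
    """Per-frame discrete-state assignments for many traces plus the model."""

    frames: pd.DataFrame
    model: dict  # serialized HMMModelSpec (see schemes.HMMModelSpec.to_dict)

    def __post_init__(self):
        missing = [c for c in _IDEAL_COLUMNS if c not in self.frames.columns]
        if missing:
            raise TraceFormatError(f"idealization table missing columns: {missing}")
        self.frames = self.frames[_IDEAL_COLUMNS].reset_index(drop=True)
        n_states = len(self.model.get("state_labels", []))
        si = self.frames["state_index"]
        if len(si) and (si.min() < 0 or (n_states and si.max() >= n_states)):
            raise TraceFormatError("state_index outside model range")
        for tid, sub in self.frames.groupby("trace_id", sort=False):
            fr = sub["frame"].to_numpy()
            if fr[0] != 0 or np.any(np.diff(fr) != 1):
                raise TraceFormatError(
                    f"trace {tid!r}: idealized frames must be contiguous from 0"
                )

    def path(self, trace_id) -> np.ndarray:
        sub = self.frames[self.frames["trace_id"] == trace_id]
        if sub.empty:
            raise KeyError(trace_id)
        return sub["state_index"].to_numpy()


def _validate_trace_frames(df: pd.DataFrame, frame_interval: float) -> None:
    for col in ("time_s", "donor", "acceptor"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "trace_id"].iloc[0]
            raise TraceFormatError(f"non-numeric {col} value in trace {bad!r}")
        if not np.all(np.isfinite(vals)):
            bad = df.loc[~np.isfinite(vals), "trace_id"].iloc[0]
            raise TraceFormatError(f"non-finite {col} value in trace {bad!r}")
    dup = df.duplicated(subset=["trace_id", "frame"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicated record for trace {row['trace_id']!r} frame {int(row['frame'])}"
        )
    for tid, sub in df.groupby("trace_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
                raise NonUniformGridError(f"trace {tid!r}: non-uniform time grid")
            if abs(steps[0] - frame_interval) > 1e-9:
                raise NonUniformGridError(
                    f"trace {tid!r}: frame interval {steps[0]!r} does not match "
                    f"metadata value {frame_interval!r}"
                )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def read_traces(path) -> TraceSet:
    """Read a TSV trace table and its JSON sidecar into a validated TraceSet."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingSidecarError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = TraceMeta.from_dict(json.load(fh))
    df = pd.read_csv(path, sep="\t", dtype={"trace_id": str})
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return TraceSet(frames=pd.DataFrame(columns=_TRACE_COLUMNS), meta=meta)
    df["frame"] = df["frame"].astype(int)
    return TraceSet(frames=df, meta=meta)


def write_traces(traceset: TraceSet, path) -> Path:
    """Write the TSV trace table and JSON sidecar; returns the table path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traceset.frames.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(traceset.meta.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_idealization(path) -> IdealizedSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingSidecarError(f"missing model sidecar {sidecar}")
    with open(sidecar) as fh:
        model = json.load(fh)
    df = pd.read_csv(path, sep="\t", dtype={"trace_id": str})
    if len(df):
        df["frame"] = df["frame"].astype(int)
        df["state_index"] = df["state_index"].astype(int)
    return IdealizedSet(frames=df, model=model)


def write_idealization(ideal: IdealizedSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ideal.frames.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(ideal.model, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: dict, path) -> Path:
    """Write an analysis report as JSON (fitted parameters, SEMs, seeds)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(_jsonable(results))
    payload.setdefault("software", {"name": "ribofret", "version": __version__})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
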