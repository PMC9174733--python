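"""Reading and writing the delimited-text formats used by the pipeline.

Trajectories are CSV with header ``id,timestamp,x_m,y_m``; timestamps may
be ISO-8601 strings or epoch seconds and are normalized to epoch seconds.
Exclusion windows are CSV ``start,end,reason``; behaviour tables and
summary tables are plain CSV with a header row; configs are YAML or JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ExclusionWindow
from .trajectory import Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_exclusion_windows",
    "write_table",
    "read_table",
    "load_config",
    "dump_config",
]


class MalformedInputError(ValueError):
    """Raised for unparseable rows or duplicate timestamps, with the
    offending line numbers (1-based, header = line 1)."""


def _parse_timestamps(raw: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Epoch seconds from epoch-seconds or ISO-8601 strings; returns
    (values, bad_mask)."""
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna()
    if bad.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dt = pd.to_datetime(raw[bad], errors="coerce", utc=True)
        ok = dt.notna()
        secs = dt[ok].astype("int64") / 1e9
        num.loc[secs.index] = secs
        bad = num.isna()
    return num.to_numpy(dtype=float), bad.to_numpy()


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Parse a trajectory file into per-individual streams sorted by
    (id, timestamp). Malformed rows or duplicated timestamps within an
    individual raise :class:`MalformedInputError` naming the lines."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, skip_blank_lines=True)
    required = {"id", "timestamp", "x_m", "y_m"}
    if not required <= set(df.columns):
        raise MalformedInputError(
            f"{path}: header must contain {sorted(required)}")
    if df.empty:
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return []
    lines = df.index.to_numpy() + 2  # 1-based file lines, after header

    ts, bad_ts = _parse_timestamps(df["timestamp"])
    x = pd.to_numeric(df["x_m"], errors="coerce")
    y = pd.to_numeric(df["y_m"], errors="coerce")
    bad = bad_ts | x.isna().to_numpy() | y.isna().to_numpy() | df["id"].isna().to_numpy()
    if bad.any():
        first = lines[bad][0]
        raise MalformedInputError(
            f"{path}: {int(bad.sum())} malformed row(s); first at line {first}")
    df = df.assign(_t=ts, _x=x.to_numpy(float), _y=y.to_numpy(float),
                   _line=lines)
    df = df.sort_values(["id", "_t"], kind="mergesort")
    dup = df.duplicated(subset=["id", "_t"], keep=False)
    if dup.any():
        row = df[dup].iloc[1]
        raise MalformedInputError(
            f"{path}: duplicate timestamp for id {row['id']!r} "
            f"at line {int(row['_line'])}")
    out = []
    for iid, g in df.groupby("id", sort=True):
        t = g["_t"].to_numpy()
        # nominal rate inferred from the median sampling interval
        hz = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        out.append(Trajectory(str(iid), t, g["_x"].to_numpy(),
                              g["_y"].to_numpy(), nominal_hz=hz))
    return out


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    frames = [pd.DataFrame({"id": tr.individual_id, "timestamp": tr.t,
                            "x_m": tr.x, "y_m": tr.y})
              for tr in trajectories]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["id", "timestamp", "x_m", "y_m"]))
    df.to_csv(path, index=False)


def read_exclusion_windows(path: str | Path) -> list[ExclusionWindow]:
    df = pd.read_csv(path)
    start, _ = _parse_timestamps(df["start"])
    end, _ = _parse_timestamps(df["end"])
    reasons = df["reason"] if "reason" in df.columns else [""] * len(df)
    return [ExclusionWindow(s, e, str(r))
            for s, e, r in zip(start, end, reasons)]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
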