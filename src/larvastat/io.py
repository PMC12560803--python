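"""CSV interchange and JSON result serialization.

Trace tables mirror post-processing exports of video-tracking systems
(long format, one row per larva-second); spike-count tables mirror
post-spike-sorting exports (one row per unit, one column per recording
segment).  Validation reports offending rows by line number; every result
JSON embeds the seed and a config hash so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

TRACE_COLUMNS = [
    "experiment",
    "animal",
    "treatment",
    "time_s",
    "distance_cm",
    "dead",
    "malformed",
    "uninflated",
]
SPIKE_COLUMNS = ["unit", "well", "antagonist"] + [f"seg{i}" for i in range(1, 12)]
ANTAGONISTS = ("bicuculline", "saclofen")


def _row_label(i: int) -> str:
    # +2: header line plus 1-based numbering
    return f"line {i + 2}"


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-second locomotion trace CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table {path}: missing columns {missing}")
    bad = df.index[df["distance_cm"].astype(float) < 0]
    if len(bad):
        raise ValueError(
            f"trace table {path}: negative distance at {_row_label(int(bad[0]))}"
        )
    dup = df.duplicated(subset=["experiment", "animal", "time_s"])
    if dup.any():
        i = int(df.index[dup][0])
        raise ValueError(
            f"trace table {path}: duplicate (animal, time) at {_row_label(i)}"
        )
    for c in ("dead", "malformed", "uninflated"):
        df[c] = df[c].astype(bool)
    df["time_s"] = df["time_s"].astype(int)
    df["distance_cm"] = df["distance_cm"].astype(float)
    return df


def write_trace_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in TRACE_COLUMNS if c in df.columns])


def read_spike_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-unit spike-count CSV (11 segments)."""
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path}: missing columns {missing}")
    bad_ant = ~df["antagonist"].isin(ANTAGONISTS)
    if bad_ant.any():
        i = int(df.index[bad_ant][0])
        raise ValueError(
            f"spike table {path}: antagonist must be one of {ANTAGONISTS} "
            f"at {_row_label(i)}"
        )
    for c in SPIKE_COLUMNS[3:]:
        vals = df[c].astype(float)
        if not np.all(np.isfinite(vals)):
            i = int(df.index[~np.isfinite(vals)][0])
            raise ValueError(f"spike table {path}: non-finite count at {_row_label(i)}")
        if not np.all(vals == np.floor(vals)):
            i = int(df.index[vals != np.floor(vals)][0])
            raise ValueError(f"spike table {path}: non-integer count at {_row_label(i)}")
        if (vals < 0).any():
            i = int(df.index[vals < 0][0])
            raise ValueError(f"spike table {path}: negative count at {_row_label(i)}")
        df[c] = vals.astype(int)
    if df["unit"].duplicated().any():
        i = int(df.index[df["unit"].duplicated()][0])
        raise ValueError(f"spike table {path}: duplicate unit id at {_row_label(i)}")
    return df


def write_spike_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in SPIKE_COLUMNS if c in df.columns])


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return super().default(o)


def write_results_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder))
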