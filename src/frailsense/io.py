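"""CSV / YAML input-output for the study tables.

Position streams use the dialect ``participant_id,t_unix_s,x_m,y_m,z_m``
(one row per sample, strictly increasing time per participant). Zone
maps are YAML mappings of named metric rectangles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .errors import SchemaError
from .models import Trajectory, ZoneMap

POSITION_COLUMNS = ["participant_id", "t_unix_s", "x_m", "y_m", "z_m"]


def write_positions(trajectories: Iterable[Trajectory], path) -> None:
    frames = [tr.to_frame() for tr in trajectories]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=POSITION_COLUMNS
    )
    df.to_csv(path, index=False)


def read_positions(path) -> pd.DataFrame:
    """Read a position-stream CSV, enforcing schema and per-participant
    time monotonicity (errors carry 1-based data line numbers)."""
    df = pd.read_csv(path)
    missing = set(POSITION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col in POSITION_COLUMNS[1:]:
        bad = df.index[~pd.to_numeric(df[col], errors="coerce").notna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    for pid, sub in df.groupby("participant_id", sort=False):
        t = sub["t_unix_s"].to_numpy()
        nonmono = (t[1:] <= t[:-1]).nonzero()[0]
        if len(nonmono):
            line = int(sub.index[nonmono[0] + 1]) + 2
            raise SchemaError(
                f"{path}: non-monotone timestamp for participant {pid} at line {line}"
            )
    return df


def trajectories_from_frame(df: pd.DataFrame, label: str = "") -> dict[str, Trajectory]:
    return {
        str(pid): Trajectory.from_frame(df, pid, label=label)
        for pid in df["participant_id"].unique()
    }


def write_zonemap(zonemap: ZoneMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"zones": zonemap.to_dict()}, fh, sort_keys=True)


def read_zonemap(path) -> ZoneMap:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "zones" not in spec:
        raise SchemaError(f"{path}: expected a top-level 'zones' mapping")
    return ZoneMap.from_dict(spec["zones"])


def require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{name}: missing columns {sorted(missing)}")


def check_unique_participants(df: pd.DataFrame, name: str) -> None:
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{name}: duplicate participant id {dup.iloc[0]!r}")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
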