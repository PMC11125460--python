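"""Trajectory persistence: storage-format (.sto-style) text tables and CSV.

The storage dialect is the tab-delimited text convention of the
musculoskeletal-simulation ecosystem: a small key=value header with nRows /
nColumns, an ``endheader`` sentinel, a column-name row beginning with
``time``, then whitespace-delimited numeric rows.  Floats are written with
full round-trip precision; the reader tolerates tab or multi-space
delimiters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


class StorageParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


def write_trajectory(traj, path) -> None:
    """Write a trajectory as a storage-format text file (plus metadata in
    the header).  ``read_trajectory(write_trajectory(x))`` is lossless."""
    path = Path(path)
    df = traj.column_frame()
    lines = [path.stem]
    meta = traj.meta()
    lines.append(f"meta={json.dumps(meta)}")
    lines.append("version=1")
    lines.append("inDegrees=no")
    lines.append(f"nRows={len(df)}")
    lines.append(f"nColumns={len(df.columns)}")
    lines.append("endheader")
    lines.append("\t".join(df.columns))
    for row in df.itertuples(index=False):
        lines.append("\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_csv(traj, path) -> None:
    traj.column_frame().to_csv(path, index=False)


def read_storage(path) -> tuple[pd.DataFrame, dict]:
    """Read a storage-format file into a DataFrame plus header metadata."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict = {}
    n_rows = n_cols = None
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if s == "endheader":
            break
        if s.startswith("meta="):
            meta = json.loads(s[5:])
        elif s.startswith("nRows="):
            n_rows = int(s[6:])
        elif s.startswith("nColumns="):
            n_cols = int(s[9:])
    else:
        raise StorageParseError("missing endheader", len(lines))
    if n_rows is None or n_cols is None:
        raise StorageParseError("missing nRows/nColumns", i + 1)
    header_line = i + 1
    if header_line >= len(lines):
        raise StorageParseError("missing column header", header_line + 1)
    columns = lines[header_line].split()
    if len(columns) != n_cols:
        raise StorageParseError(
            f"header has {len(columns)} columns, expected {n_cols}",
            header_line + 1)
    if columns[0] != "time":
        raise StorageParseError("first column must be 'time'", header_line + 1)
    data = np.empty((n_rows, n_cols))
    for r in range(n_rows):
        ln = header_line + 1 + r
        if ln >= len(lines) or not lines[ln].strip():
            raise StorageParseError("truncated data section", ln + 1)
        parts = lines[ln].split()
        if len(parts) != n_cols:
            raise StorageParseError(
                f"row has {len(parts)} values, expected {n_cols}", ln + 1)
        try:
            data[r] = [float(p) for p in parts]
        except ValueError:
            raise StorageParseError("non-numeric value", ln + 1) from None
    return pd.DataFrame(data, columns=columns), meta


def read_trajectory(path):
    """Reconstruct a Trajectory from a storage file written by
    :func:`write_trajectory`."""
    from .engine import ENGINE_COORDS
    from .trajectory import Trajectory
    df, meta = read_storage(path)

    def block(prefix):
        cols = [c for c in df.columns if c.startswith(prefix)]
        return df[cols].to_numpy(), tuple(c[len(prefix):] for c in cols)

    q, _ = block("q_")
    qd, _ = block("qd_")
    act, names = block("act_")
    exc, _ = block("exc_")
    force, _ = block("force_")
    cn, _ = block("contact_normal_")
    ct, _ = block("contact_tangential_")
    t = df["time"].to_numpy()
    dt = meta.get("dt", float(t[1] - t[0]) if len(t) > 1 else 1e-3)
    return Trajectory(
        t=t, q=q, qdot=qd, act=act, exc=exc, muscle_force=force,
        contact_normal=cn, contact_tangential=ct,
        com=df[["com_x", "com_y"]].to_numpy(),
        com_vel=df[["com_vx", "com_vy"]].to_numpy(),
        foot_com=df[["foot_com_x", "foot_com_vx"]].to_numpy(),
        cop=df["cop_x"].to_numpy(),
        platform=df[["platform_x", "platform_vx"]].to_numpy(),
        grf=df[["grf_x", "grf_y"]].to_numpy(),
        dt=dt, t_term=meta.get("t_term", float(t[-1])),
        fell=bool(meta.get("fell", False)),
        effort_integral=meta.get("effort_integral", float("nan")),
        dof_integral=meta.get("dof_integral", float("nan")),
        muscle_names=names,
        condition_id=meta.get("condition_id", ""),
        seed=meta.get("seed"))
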