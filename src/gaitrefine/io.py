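"""Readers/writers for OpenSim storage (.sto) files and plain CSV.

The .sto dialect handled here is the one produced by OpenSim analysis
tools: free-form header lines including ``nRows=``/``nColumns=``, a line
``endheader``, then a tab-separated numeric body whose first column is
``time``.  Values are written with 10 significant digits so a write/read
round trip is stable to at least 9 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .cycles import ActivationCycle

__all__ = ["write_sto", "read_sto", "write_csv", "read_csv", "cycle_to_frame", "frame_to_cycle"]

_FLOAT_FMT = "%.10g"


def cycle_to_frame(cycle: ActivationCycle) -> pd.DataFrame:
    """Tabulate a cycle as time + one column per muscle."""
    data = {"time": cycle.sample_times}
    for name, row in zip(cycle.muscle_names, cycle.values):
        data[name] = row
    return pd.DataFrame(data)


def frame_to_cycle(frame: pd.DataFrame, **identity) -> ActivationCycle:
    """Build a cycle from a time + channels table (inverse of cycle_to_frame)."""
    if "time" not in frame.columns:
        raise ValueError("table must contain a 'time' column")
    names = [c for c in frame.columns if c != "time"]
    return ActivationCycle(
        values=frame[names].to_numpy().T,
        sample_times=frame["time"].to_numpy(),
        muscle_names=names,
        **identity,
    )


def write_sto(path: str | Path, frame: pd.DataFrame, name: str = "activations") -> None:
    """Write a time-series table in OpenSim storage format."""
    if "time" not in frame.columns:
        raise ValueError("table must contain a 'time' column")
    cols = ["time"] + [c for c in frame.columns if c != "time"]
    frame = frame[cols]
    buf = _io.StringIO()
    buf.write(f"{name}\n")
    buf.write(f"version=1\n")
    buf.write(f"nRows={len(frame)}\n")
    buf.write(f"nColumns={len(cols)}\n")
    buf.write("inDegrees=no\n")
    buf.write("endheader\n")
    buf.write("\t".join(cols) + "\n")
    for row in frame.itertuples(index=False):
        buf.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_sto(path: str | Path) -> pd.DataFrame:
    """Read an OpenSim storage file into a time + channels table."""
    lines = Path(path).read_text().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip().lower() == "endheader")
    except StopIteration:
        raise ValueError(f"{path}: no 'endheader' line — not a .sto file") from None
    header = lines[end + 1].rstrip("\n").split("\t")
    body = "\n".join(lines[end + 2 :])
    frame = pd.read_csv(_io.StringIO(body), sep="\t", names=header)
    if header[0] != "time":
        raise ValueError(f"{path}: first column is {header[0]!r}, expected 'time'")
    return frame


def write_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Write a time + channels table as plain CSV."""
    if "time" not in frame.columns:
        raise ValueError("table must contain a 'time' column")
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ValueError(f"{path}: no 'time' column")
    return frame


def read_table(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .sto via the storage parser, otherwise CSV."""
    p = Path(path)
    if p.suffix.lower() == ".sto":
        return read_sto(p)
    return read_csv(p)
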