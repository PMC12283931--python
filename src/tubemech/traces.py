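"""Filament trace containers and plain-text trace-table I/O.

A :class:`FilamentTrace` holds the ordered backbone node coordinates of one
filament in one movie frame; a :class:`TrackStack` collects the traces of one
filament across frames and is the unit over which the mean-square end-to-end
distance is averaged.  Traces are exchanged on disk as tab-separated tables
with columns ``filament_id, frame, node_index, x, y, unit`` — one row per
backbone node — which is also the format the tracker emits and the simulator
writes, so externally produced (e.g. snake-style) traces can enter the
pipeline at the same point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilamentTrace",
    "TrackStack",
    "read_trace_table",
    "write_trace_table",
    "read_snakes",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ["filament_id", "frame", "node_index", "x", "y", "unit"]

#: Recognised coordinate units for trace nodes.
VALID_UNITS = ("um", "px")


@dataclass(frozen=True)
class FilamentTrace:
    """Ordered 2D backbone nodes of one filament in one frame.

    Parameters
    ----------
    filament_id : int or str
        Identifier shared by all traces of the same filament.
    frame : int
        Frame index within the movie.
    nodes : ndarray, shape (n, 2)
        Node coordinates ``(x, y)``, at least two nodes, with no two
        consecutive nodes coincident.
    unit : {"um", "px"}
        Unit of the node coordinates.
    """

    filament_id: int | str
    frame: int
    nodes: np.ndarray
    unit: str = "um"
    arc_positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ValueError("nodes must be an (n, 2) array of (x, y)")
        if nodes.shape[0] < 2:
            raise ValueError("a trace needs at least 2 nodes")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive trace nodes must be distinct")
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arc_positions", arc)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def with_nodes(self, nodes: np.ndarray) -> "FilamentTrace":
        """Copy of this trace with replaced node coordinates."""
        return dataclasses.replace(self, nodes=nodes)


@dataclass(frozen=True)
class TrackStack:
    """All traces of one filament across frames, sorted by frame index."""

    filament_id: int | str
    traces: tuple[FilamentTrace, ...]

    def __post_init__(self) -> None:
        traces = tuple(sorted(self.traces, key=lambda t: t.frame))
        if not traces:
            raise ValueError("a TrackStack needs at least one trace")
        for t in traces:
            if t.filament_id != self.filament_id:
                raise ValueError(
                    f"trace filament_id {t.filament_id!r} does not match "
                    f"stack id {self.filament_id!r}"
                )
        frames = [t.frame for t in traces]
        if len(set(frames)) != len(frames):
            raise ValueError("duplicate frame indices in TrackStack")
        object.__setattr__(self, "traces", traces)

    @property
    def n_frames(self) -> int:
        return len(self.traces)

    @property
    def frames(self) -> np.ndarray:
        return np.array([t.frame for t in self.traces])

    @property
    def n_gaps(self) -> int:
        """Number of missing frames inside the track's frame span."""
        f = self.frames
        return int(f[-1] - f[0] + 1 - len(f))

    @property
    def unit(self) -> str:
        return self.traces[0].unit


def _stacks_to_frame(items: Iterable[TrackStack | FilamentTrace]) -> pd.DataFrame:
    rows = []
    for item in items:
        traces = item.traces if isinstance(item, TrackStack) else (item,)
        for t in traces:
            n = t.n_nodes
            rows.append(
                pd.DataFrame(
                    {
                        "filament_id": [t.filament_id] * n,
                        "frame": [t.frame] * n,
                        "node_index": np.arange(n),
                        "x": t.nodes[:, 0],
                        "y": t.nodes[:, 1],
                        "unit": [t.unit] * n,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_trace_table(
    items: Iterable[TrackStack | FilamentTrace], path: str | Path
) -> None:
    """Write stacks or traces to a tab-separated trace table."""
    _stacks_to_frame(items).to_csv(path, sep="\t", index=False)


def _frame_to_stacks(df: pd.DataFrame) -> list[TrackStack]:
    stacks = []
    for fid, fgroup in df.groupby("filament_id", sort=True):
        traces = []
        for fr, ngroup in fgroup.groupby("frame", sort=True):
            ngroup = ngroup.sort_values("node_index")
            unit = str(ngroup["unit"].iloc[0])
            traces.append(
                FilamentTrace(
                    filament_id=fid,
                    frame=int(fr),
                    nodes=ngroup[["x", "y"]].to_numpy(float),
                    unit=unit,
                )
            )
        stacks.append(TrackStack(filament_id=fid, traces=tuple(traces)))
    return stacks


def read_trace_table(path: str | Path) -> list[TrackStack]:
    """Read a tab-separated trace table into TrackStacks."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    return _frame_to_stacks(df)


def read_snakes(
    path: str | Path,
    columns: Sequence[str] = ("filament_id", "frame", "x", "y"),
    unit: str = "px",
) -> list[TrackStack]:
    """Read snake-style whitespace-delimited trace exports.

    Tolerant reader for externally tracked filaments (e.g. active-contour
    "snake" exports): any whitespace-delimited numeric file whose columns can
    be mapped onto ``filament_id``/``frame``/``x``/``y`` via *columns*.
    Lines starting with ``#`` are ignored; node order is taken as row order
    within each (filament, frame) block.
    """
    for required in ("filament_id", "frame", "x", "y"):
        if required not in columns:
            raise ValueError(f"columns mapping must include {required!r}")
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=list(columns)
    )
    df["node_index"] = df.groupby(["filament_id", "frame"]).cumcount()
    df["unit"] = unit
    return _frame_to_stacks(df[TRACE_COLUMNS])
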