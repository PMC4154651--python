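"""File formats: event tables, trace matrices, weighted edge lists.

All formats are plain delimited text so recordings and results stay
portable and diffable:

* events — two tab-separated columns ``node_id<TAB>onset_seconds``, one
  optional header line;
* traces — a ``# frame_rate=<fps>`` comment line, a header of node ids,
  then one tab-separated row per frame;
* networks — ``src<TAB>dst<TAB>weight`` with weights printed at 12
  significant digits, so write -> read round-trips exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EventTrain
from .network import DirectedWeightedNetwork
from .synth import FluorescenceMovie


def read_events(path: "str | Path") -> EventTrain:
    """Read an event table (node_id, onset_seconds).

    The header line is optional; rows are sorted by time; duplicated
    (node, time) rows are collapsed with a warning; unparseable rows raise
    with their line number.
    """
    path = Path(path)
    nodes: list[str] = []
    times: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2+ columns, got {line!r}")
            try:
                t = float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise ValueError(
                    f"{path}:{lineno}: cannot parse onset time {parts[1]!r}"
                ) from None
            nodes.append(parts[0])
            times.append(t)
    if not nodes:
        warnings.warn(f"{path}: no events found", stacklevel=2)
        return EventTrain(np.array([], dtype=object), np.array([]))
    df = pd.DataFrame({"node": nodes, "time": times})
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        warnings.warn(
            f"{path}: collapsed {n_before - len(df)} duplicate (node, time) rows",
            stacklevel=2,
        )
    return EventTrain(df["node"].to_numpy(dtype=object), df["time"].to_numpy())


def write_events(train: EventTrain, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node_id\tonset_seconds\n")
        for node, t in zip(train.node_ids, train.times):
            fh.write(f"{node}\t{t:.9f}\n")


def read_network(path: "str | Path") -> DirectedWeightedNetwork:
    """Read a weighted directed edge list (src, dst, weight)."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {line!r}")
            try:
                w = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(
                    f"{path}:{lineno}: cannot parse weight {parts[2]!r}"
                ) from None
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            edges.append((parts[0], parts[1], w))
    return DirectedWeightedNetwork.from_edges(edges)


def write_network(net: DirectedWeightedNetwork, path: "str | Path") -> None:
    """Write the nonzero links as an edge list, 12 significant digits."""
    path = Path(path)
    src, dst = np.nonzero(net.w)
    with path.open("w") as fh:
        fh.write("src\tdst\tweight\n")
        for i, j in zip(src, dst):
            fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\t{net.w[i, j]:.12g}\n")


def write_network_graphml(net: DirectedWeightedNetwork, path: "str | Path") -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), str(path))


def read_traces(path: "str | Path") -> FluorescenceMovie:
    """Read a trace matrix: ``# frame_rate=<fps>`` line, node-id header,
    then one row of fluorescence values per frame."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "frame_rate=" not in first:
            raise ValueError(f"{path}: first line must carry '# frame_rate=<fps>'")
        frame_rate = float(first.split("frame_rate=")[1].split()[0])
        node_ids = fh.readline().split()
        values = np.loadtxt(fh)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[1] != len(node_ids):
        raise ValueError(
            f"{path}: {len(node_ids)} node ids but {values.shape[1]} trace columns"
        )
    return FluorescenceMovie(values=values, frame_rate=frame_rate, node_ids=node_ids)


def write_traces(movie: FluorescenceMovie, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_rate={movie.frame_rate:g}\n")
        fh.write("\t".join(movie.node_ids) + "\n")
        np.savetxt(fh, movie.values, fmt="%.6f", delimiter="\t")
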