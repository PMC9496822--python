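"""Plain-text file formats: networks, partitions, signals, traces.

All user-facing files use node *names*; integer indices are internal.
Formats are deliberately simple: edge-list TSV (``a<TAB>b``), dense 0/1
matrix CSV with a node-name header, partition TSV (``node<TAB>community``),
trace CSV, and signal CSV (header row of channel names, then one row of
samples per channel).  An HDF5-style container with datasets ``data``,
``fs``, ``channels`` is supported for signals as well.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .network import BinaryNetwork, Partition
from .signals import SignalEpoch


def read_network(path: str | Path, format: str = "edgelist") -> BinaryNetwork:
    """Read a network from an edge-list TSV or a dense matrix CSV.

    Edge list: one ``node_a<TAB>node_b`` pair per line; nodes ordered by
    first appearance; duplicate lines collapse to one edge (warning);
    self-loops are dropped (warning).  Matrix: header row of node names,
    one row per node; must be symmetric 0/1.
    """
    path = Path(path)
    if format == "edgelist":
        names: list[str] = []
        index: dict[str, int] = {}
        edges: set[tuple[int, int]] = set()
        dupes = 0
        loops = 0
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidInputError(f"bad edge line: {line!r}")
            for p in parts:
                if p not in index:
                    index[p] = len(names)
                    names.append(p)
            u, v = index[parts[0]], index[parts[1]]
            if u == v:
                loops += 1
                continue
            e = (u, v) if u < v else (v, u)
            if e in edges:
                dupes += 1
            edges.add(e)
        if dupes:
            warnings.warn(f"{dupes} duplicate edge line(s) collapsed", stacklevel=2)
        if loops:
            warnings.warn(f"{loops} self-loop(s) dropped", stacklevel=2)
        if not names:
            raise InvalidInputError(f"no edges found in {path}")
        return BinaryNetwork.from_edges(len(names), sorted(edges), names)
    elif format == "matrix":
        with path.open() as fh:
            reader = csv.reader(fh)
            header = next(reader)
            rows = [[float(x) for x in row] for row in reader if row]
        names = [h.strip() for h in header]
        mat = np.asarray(rows)
        if mat.shape != (len(names), len(names)):
            raise InvalidInputError("matrix shape does not match header")
        if not np.allclose(mat, mat.T, atol=1e-9):
            raise InvalidInputError("adjacency matrix must be symmetric")
        if np.any(np.diag(mat) != 0):
            warnings.warn("nonzero diagonal ignored (self-loops dropped)", stacklevel=2)
        edges = [
            (i, j)
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if mat[i, j] != 0
        ]
        return BinaryNetwork.from_edges(len(names), edges, names)
    raise InvalidInputError(f"unknown network format: {format!r}")


def write_network(path: str | Path, network: BinaryNetwork, format: str = "edgelist") -> None:
    path = Path(path)
    if format == "edgelist":
        lines = [
            f"{network.node_names[u]}\t{network.node_names[v]}"
            for u, v in network.edges
        ]
        path.write_text("\n".join(lines) + "\n")
    elif format == "matrix":
        n = network.n_nodes
        mat = np.zeros((n, n), dtype=int)
        for u, v in network.edges:
            mat[u, v] = mat[v, u] = 1
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(network.node_names)
            writer.writerows(mat.tolist())
    else:
        raise InvalidInputError(f"unknown network format: {format!r}")


def write_partition(
    path: str | Path, partition: Partition, node_names: Sequence[str]
) -> None:
    """TSV ``node_name<TAB>community_id``, communities 0..k-1 by smallest member."""
    if len(node_names) != partition.n_nodes:
        raise InvalidInputError("node_names length must match partition size")
    labels = partition.labels()
    lines = [f"{node_names[i]}\t{labels[i]}" for i in range(partition.n_nodes)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_partition(
    path: str | Path, node_names: Sequence[str] | None = None
) -> tuple[Partition, tuple[str, ...]]:
    """Read a partition TSV; returns (partition, node name order from file).

    If ``node_names`` is given (e.g. from a network), the file's names
    must match that set and the partition is indexed in that order.
    """
    path = Path(path)
    rows: list[tuple[str, int]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InvalidInputError(f"bad partition line: {line!r}")
        rows.append((parts[0], int(parts[1])))
    if not rows:
        raise InvalidInputError(f"empty partition file: {path}")
    file_names = [r[0] for r in rows]
    if len(set(file_names)) != len(file_names):
        raise InvalidInputError("duplicate node names in partition file")
    if node_names is not None:
        if set(node_names) != set(file_names):
            raise InvalidInputError("partition node names do not match network")
        by_name = dict(rows)
        labels = [by_name[n] for n in node_names]
        return Partition.from_labels(labels), tuple(node_names)
    return Partition.from_labels([r[1] for r in rows]), tuple(file_names)


def write_trace(path: str | Path, trace: Sequence[dict]) -> None:
    """Per-generation trace CSV: generation, best_q, mean_q, pc, pm."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["generation", "best_q", "mean_q", "pc", "pm"])
        for row in trace:
            writer.writerow(
                [row["generation"], row["best_q"], row["mean_q"], row["pc"], row["pm"]]
            )


def read_signals(path: str | Path, fs: float | None = None) -> SignalEpoch:
    """Read a signal epoch from CSV/TSV or an HDF5 container.

    CSV/TSV: first line is the comma/tab-separated channel names; each
    following line holds one channel's samples, in header order.  ``fs``
    must be supplied.  HDF5 (suffix .h5/.hdf5): datasets ``data``
    (channels x samples), ``fs`` (scalar), ``channels`` (names).
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            fs_file = float(np.asarray(f["fs"]).reshape(()))
            channels = [
                c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]
            ]
        return SignalEpoch(data=data, fs=fs_file, channel_names=channels)
    if fs is None:
        raise InvalidInputError("sampling rate fs is required for text signal files")
    text = path.read_text().splitlines()
    if not text:
        raise InvalidInputError(f"empty signal file: {path}")
    delim = "\t" if "\t" in text[0] else ","
    names = [c.strip() for c in text[0].split(delim)]
    rows = [
        [float(x) for x in line.split(delim)]
        for line in text[1:]
        if line.strip()
    ]
    if len(rows) != len(names):
        raise InvalidInputError(
            f"expected {len(names)} channel rows, found {len(rows)}"
        )
    return SignalEpoch(data=np.asarray(rows), fs=fs, channel_names=names)


def write_signals(path: str | Path, epoch: SignalEpoch) -> None:
    """Write a signal epoch as CSV (or HDF5 if the suffix is .h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=epoch.data)
            f.create_dataset("fs", data=epoch.fs)
            f.create_dataset(
                "channels", data=np.array([n.encode() for n in epoch.channel_names])
            )
        return
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(epoch.channel_names)
        for row in epoch.data:
            writer.writerow([repr(float(x)) for x in row])
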