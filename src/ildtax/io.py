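"""Delimited-text I/O for surveys, labels, linkage trees and score files.

The survey format is a plain delimited table: a header row of ILD levels in
dB, one row per cell, first column the cell id.  Headers may be written with
levels descending; they are normalized to ascending order on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import LinkageTree
from .core import ILDAxis, ILDDataset

__all__ = [
    "read_ild_matrix",
    "write_ild_matrix",
    "read_labels",
    "write_labels",
    "write_merge_table",
    "tree_to_newick",
]


def read_ild_matrix(path: str | Path, sep: str = "\t") -> ILDDataset:
    """Read a cell x ILD-level spike-count table.

    Validates a uniform monotone axis (descending headers are flipped to
    ascending) and names the offending row/column on bad cells.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two ILD level columns")
    try:
        levels = np.asarray([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: header is not numeric ILD levels ({exc})") from None
    if np.all(np.diff(levels) < 0):  # descending header -> normalize
        df = df.iloc[:, ::-1]
        levels = levels[::-1]
    axis = ILDAxis(levels)
    bad = df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing/non-numeric value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    return ILDDataset(counts, axis, [str(i) for i in df.index])


def write_ild_matrix(dataset: ILDDataset, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        dataset.counts,
        index=pd.Index(dataset.cell_ids, name="cell_id"),
        columns=[format(v, "g") for v in dataset.axis.levels],
    )
    df.to_csv(path, sep=sep)


def write_labels(
    cell_ids: list[str], labels: np.ndarray, path: str | Path, sep: str = "\t"
) -> None:
    pd.DataFrame({"cell_id": cell_ids, "group": labels}).to_csv(path, sep=sep, index=False)


def read_labels(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_merge_table(tree: LinkageTree, path: str | Path, sep: str = "\t") -> None:
    """Write the 4-column merge table (left, right, height, size), bit-exact."""
    with open(path, "w") as fh:
        fh.write(sep.join(["left", "right", "height", "size"]) + "\n")
        for left, right, height, size in tree.merges:
            fh.write(sep.join([str(int(left)), str(int(right)), repr(float(height)), str(int(size))]) + "\n")


def tree_to_newick(tree: LinkageTree, leaf_names: list[str] | None = None) -> str:
    """Render the dendrogram as Newick; branch lengths are height differences."""
    names = leaf_names or [f"cell{i + 1:03d}" for i in range(tree.n)]
    if len(names) != tree.n:
        raise ValueError("leaf_names length does not match tree size")
    height = {i: 0.0 for i in range(tree.n)}
    rep = dict(enumerate(names))
    for step, (left, right, h, _size) in enumerate(tree.merges):
        li, ri = int(left), int(right)
        node = tree.n + step
        bl = h - height[li]
        br = h - height[ri]
        rep[node] = f"({rep[li]}:{bl:.10g},{rep[ri]}:{br:.10g})"
        height[node] = h
    return rep[tree.n + len(tree.merges) - 1] + ";"
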