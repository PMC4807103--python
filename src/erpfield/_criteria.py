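"""Run-length and connected-component primitives shared by the statistics.

These implement the two persistence criteria used throughout: temporal runs
of contiguous significant samples, and spatial groups of contiguous
significant electrodes/solution points on an adjacency graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["find_runs", "enforce_min_run", "connected_components"]


def find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``(start, stop)`` index ranges of True runs in a 1-D mask."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 1:
        raise ValueError("find_runs expects a 1-D mask")
    edges = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if m.size and m[0]:
        starts.insert(0, 0)
    if m.size and m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))


def enforce_min_run(mask: np.ndarray, min_run: int, *, axis: int = -1) -> np.ndarray:
    """Clear True runs shorter than ``min_run`` along ``axis``; keep the rest
    intact."""
    m = np.asarray(mask, dtype=bool)
    out = np.moveaxis(m.copy(), axis, -1)
    flat = out.reshape(-1, out.shape[-1])
    for row in flat:
        for start, stop in find_runs(row):
            if stop - start < min_run:
                row[start:stop] = False
    return np.moveaxis(flat.reshape(out.shape), -1, axis)


def connected_components(
    nodes, neighbors: tuple[tuple[int, ...], ...]
) -> list[list[int]]:
    """Connected components of the subgraph induced by ``nodes``.

    ``neighbors`` is the full graph's adjacency list; only edges with both
    ends in ``nodes`` count.  Components are returned as sorted index lists.
    """
    node_set = set(int(i) for i in nodes)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in sorted(node_set):
        if start in seen:
            continue
        stack = [start]
        comp = []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in neighbors[i]:
                if j in node_set and j not in seen:
                    seen.add(j)
                    stack.append(j)
        comps.append(sorted(comp))
    return comps
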