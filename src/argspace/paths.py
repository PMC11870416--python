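"""Sample paths through an ARG and their shared-time matrices.

A *sample path* runs from a sample up to a root; samples below recombination
nodes have several.  The path matrix ``Sp`` holds the pairwise shared times
between paths: the summed lengths of the edges two paths traverse in common.
``σ²Sp`` is the covariance of the path-tip locations when every edge's
displacement is drawn independently — the unconditioned model the whole
likelihood machinery is built on.

The full path set grows like 2^k in the number k of recombination nodes along
a lineage, but a minimal linearly-sufficient subset has exactly
``ns + (#recombination nodes)`` members and is constructed here in a single
tip-to-root traversal: at a recombination node every lineage follows the
smaller-id parent and exactly one duplicate is routed to the other parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arg import ARGError, SpatialARG

__all__ = [
    "PathSet",
    "SharedTimeMatrix",
    "enumerate_all_paths",
    "minimal_paths",
    "shared_times",
    "ancestor_shared_times",
    "canonical_path",
]


@dataclass
class PathSet:
    """Sample-to-root paths with their incidence matrices.

    ``P`` (np × ns) pairs each path with the sample it starts at; ``R``
    (np × nr) pairs each path with the root it terminates at.  Each row of
    P and of R has exactly one 1.
    """

    paths: list[tuple[int, ...]]        # node ids, sample -> root
    sample_ids: list[int]
    root_ids: list[int]
    P: np.ndarray
    R: np.ndarray
    minimal: bool

    @property
    def np_(self) -> int:
        return len(self.paths)

    def labels(self) -> list[str]:
        counts: dict[int, int] = {}
        out = []
        for path in self.paths:
            s = path[0]
            k = counts.get(s, 0)
            counts[s] = k + 1
            out.append(f"sample{s}.{k}")
        return out


@dataclass
class SharedTimeMatrix:
    """Symmetric PSD matrix of shared times (generations) between paths."""

    Sp: np.ndarray
    path_set: PathSet

    def to_frame(self) -> pd.DataFrame:
        labels = self.path_set.labels()
        return pd.DataFrame(self.Sp, index=labels, columns=labels)


def _incidence(paths, sample_ids, root_ids):
    P = np.zeros((len(paths), len(sample_ids)))
    R = np.zeros((len(paths), len(root_ids)))
    scol = {s: j for j, s in enumerate(sample_ids)}
    rcol = {r: j for j, r in enumerate(root_ids)}
    for i, path in enumerate(paths):
        P[i, scol[path[0]]] = 1.0
        R[i, rcol[path[-1]]] = 1.0
    return P, R


def enumerate_all_paths(arg: SpatialARG, max_paths: int = 100_000) -> PathSet:
    """Every distinct sample-to-root path, by depth-first branching at each
    recombination node walking rootward.

    Raises if the path count would exceed ``max_paths`` (use
    :func:`minimal_paths` instead — it grows linearly).
    """
    paths: list[tuple[int, ...]] = []
    for s in arg.sample_ids:
        stack = [(s,)]
        while stack:
            path = stack.pop()
            parents = arg.parents_of(path[-1])
            if not parents:
                paths.append(path)
                if len(paths) > max_paths:
                    raise ARGError(
                        f"more than {max_paths} sample paths; "
                        "use minimal_paths instead"
                    )
            else:
                for p in reversed(parents):
                    stack.append(path + (p,))
    roots = arg.roots
    P, R = _incidence(paths, arg.sample_ids, roots)
    return PathSet(paths, arg.sample_ids, roots, P, R, minimal=False)


def minimal_paths(arg: SpatialARG) -> PathSet:
    """A linearly-sufficient path set of size ``ns + #recombination nodes``.

    Single tip-to-root traversal: nodes are processed in increasing
    (time, id) order; lineages sitting at a node all continue to its
    smaller-id parent, and at a recombination node one duplicate (of the
    lowest-index lineage) is routed to the larger-id parent.  The sample
    matrix induced by this set equals that of the full path set.
    """
    at_node: dict[int, list[int]] = {}
    lineage_paths: list[list[int]] = []
    for s in arg.sample_ids:
        at_node.setdefault(s, []).append(len(lineage_paths))
        lineage_paths.append([s])
    finished: list[int] = []
    for v in arg.nodes_by_time():
        here = at_node.pop(v, None)
        if not here:
            continue
        parents = arg.parents_of(v)
        if not parents:
            finished.extend(here)
            continue
        if len(parents) == 2:
            dup = list(lineage_paths[here[0]])
            dup.append(parents[1])
            at_node.setdefault(parents[1], []).append(len(lineage_paths))
            lineage_paths.append(dup)
        for idx in here:
            lineage_paths[idx].append(parents[0])
        at_node.setdefault(parents[0], []).extend(here)
    # original sample lineages first (in sample order), duplicates after,
    # in creation order
    order = sorted(finished)
    paths = [tuple(lineage_paths[i]) for i in order]
    roots = arg.roots
    P, R = _incidence(paths, arg.sample_ids, roots)
    return PathSet(paths, arg.sample_ids, roots, P, R, minimal=True)


def _path_edge_sets(paths):
    return [
        {(path[i], path[i + 1]) for i in range(len(path) - 1)} for path in paths
    ]


def shared_times(arg: SpatialARG, paths: PathSet) -> SharedTimeMatrix:
    """Shared-time matrix: entry (i, j) is the total length of the edges
    traversed by both path i and path j."""
    edge_sets = _path_edge_sets(paths.paths)
    n = len(edge_sets)
    Sp = np.zeros((n, n))
    # accumulate per edge over the paths containing it
    edge_to_paths: dict[tuple[int, int], list[int]] = {}
    for i, es in enumerate(edge_sets):
        for e in es:
            edge_to_paths.setdefault(e, []).append(i)
    for e, idx in edge_to_paths.items():
        ln = arg.edge_length(*e)
        ix = np.array(idx)
        Sp[np.ix_(ix, ix)] += ln
    return SharedTimeMatrix(Sp, paths)


def canonical_path(arg: SpatialARG, node: int) -> tuple[int, ...]:
    """Deterministic node-to-root path: always take the smaller-id parent."""
    path = [int(node)]
    while True:
        parents = arg.parents_of(path[-1])
        if not parents:
            return tuple(path)
        path.append(parents[0])


def ancestor_shared_times(
    arg: SpatialARG, node: int, paths: PathSet
) -> tuple[np.ndarray, float, int]:
    """Shared times between one node-to-root path and each sample path.

    Returns ``(sa, ta, root_index)`` where ``sa[i]`` is the shared time of the
    node's canonical path with sample path i, ``ta`` is the time from the node
    up to its root, and ``root_index`` indexes that root in ``paths.root_ids``.
    The downstream conditional mean/variance are invariant to the path choice;
    the smaller-parent-id rule just makes output deterministic.
    """
    node = int(node)
    if node not in arg._times:
        raise ARGError(f"node {node} not in ARG")
    apath = canonical_path(arg, node)
    root = apath[-1]
    ta = arg.node_time(root) - arg.node_time(node)
    if ta < 0:
        raise ARGError(f"node {node} is older than its root")
    a_edges = {(apath[i], apath[i + 1]) for i in range(len(apath) - 1)}
    sa = np.zeros(paths.np_)
    for i, es in enumerate(_path_edge_sets(paths.paths)):
        sa[i] = sum(arg.edge_length(*e) for e in (a_edges & es))
    return sa, ta, paths.root_ids.index(root)
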