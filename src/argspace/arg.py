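"""Ancestral recombination graphs with sample locations.

A :class:`SpatialARG` couples the genealogical graph of a recombining sample
(nodes with times, edges with genome intervals) to the observed geographic
coordinates of the sampled genomes.  Time is measured in generations before
the present (0 = present, increasing into the past) and genome intervals are
0-based half-open ``[left, right)`` in base pairs, following tree-sequence
conventions.

Node roles are assigned structurally rather than from flags so that both full
and simplified ARGs work: a node with two distinct parents is a recombination
node, a node with no parents is a root.  Each node represents a haploid
genome; diploid individuals appear as two sample nodes sharing a coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tskit

__all__ = [
    "SpatialARG",
    "LoopConstraint",
    "load_arg",
    "chop_arg",
    "find_loops",
    "simplify_arg",
]


class ARGError(ValueError):
    """Raised when an ARG or its location table fails validation."""


@dataclass
class LoopConstraint:
    """One meeting constraint created by a recombination node.

    ``left_path`` and ``right_path`` run from the loop's top node down to the
    recombination node; under the model the summed displacements along the two
    sides must be equal.
    """

    recombination_node: int
    top_node: int
    left_path: list[tuple[int, int]]   # (child, parent) edges, top -> bottom
    right_path: list[tuple[int, int]]


class SpatialARG:
    """An ARG plus sample locations.

    Parameters
    ----------
    nodes:
        DataFrame indexed by node id with columns ``time`` (generations before
        present) and ``is_sample`` (bool).
    edges:
        DataFrame with columns ``parent``, ``child``, ``left``, ``right``.
        Multiple rows per (child, parent) pair are allowed and are merged for
        graph purposes; their genome intervals are kept.
    locations:
        DataFrame indexed by node id with columns ``x`` (and optionally ``y``),
        one row per sample node.
    sequence_length:
        Total genome length in base pairs; inferred from edges if omitted.
    """

    def __init__(self, nodes, edges, locations, sequence_length=None, validate=True):
        self.nodes = nodes.copy()
        self.nodes.index.name = "id"
        self.edges = edges.reset_index(drop=True).copy()
        self.locations = locations.copy()
        self.locations.index.name = "node_id"
        if sequence_length is None:
            sequence_length = float(self.edges["right"].max()) if len(self.edges) else 1.0
        self.sequence_length = float(sequence_length)
        self._build_adjacency()
        if validate:
            self._validate()

    # ------------------------------------------------------------------ setup

    def _build_adjacency(self):
        parents: dict[int, list[int]] = {}
        children: dict[int, list[int]] = {}
        intervals: dict[tuple[int, int], list[tuple[float, float]]] = {}
        times = self.nodes["time"]
        for row in self.edges.itertuples(index=False):
            key = (int(row.child), int(row.parent))
            if key not in intervals:
                intervals[key] = []
                parents.setdefault(key[0], []).append(key[1])
                children.setdefault(key[1], []).append(key[0])
            intervals[key].append((float(row.left), float(row.right)))
        self._parents = {v: sorted(ps) for v, ps in parents.items()}
        self._children = {v: sorted(cs) for v, cs in children.items()}
        self._intervals = intervals
        self._times = times.to_dict()
        self._edge_len = {
            (c, p): self._times[p] - self._times[c] for (c, p) in intervals
        }

    def _validate(self):
        t = self.nodes["time"]
        if (t < 0).any():
            raise ARGError("node times must be non-negative")
        for (c, p) in self._intervals:
            if c not in self._times or p not in self._times:
                raise ARGError(f"edge ({c}->{p}) references unknown node")
            if self._times[p] <= self._times[c]:
                raise ARGError(
                    f"edge ({c}->{p}): parent time {self._times[p]} must exceed "
                    f"child time {self._times[c]}"
                )
        sample_set = set(self.sample_ids)
        loc_set = set(int(i) for i in self.locations.index)
        missing = sample_set - loc_set
        if missing:
            raise ARGError(f"missing location for sample node(s) {sorted(missing)}")
        extra = loc_set - sample_set
        if extra:
            raise ARGError(f"location table has non-sample node(s) {sorted(extra)}")
        if self.ndim not in (1, 2):
            raise ARGError("locations must have columns x or x,y")
        for v, ps in self._parents.items():
            if len(ps) > 2:
                raise ARGError(
                    f"node {v} has {len(ps)} parents; at most 2 are allowed "
                    "(is this graph an ARG?)"
                )

    # ------------------------------------------------------------- properties

    @property
    def sample_ids(self) -> list[int]:
        return sorted(int(i) for i in self.nodes.index[self.nodes["is_sample"]])

    @property
    def ns(self) -> int:
        return len(self.sample_ids)

    @property
    def ndim(self) -> int:
        return 2 if "y" in self.locations.columns else 1

    @property
    def locations_array(self) -> np.ndarray:
        """ns × d array of sample coordinates, rows aligned with sample_ids."""
        cols = ["x", "y"][: self.ndim]
        return self.locations.loc[self.sample_ids, cols].to_numpy(float)

    @property
    def roots(self) -> list[int]:
        return sorted(v for v in self.nodes.index if not self._parents.get(int(v)))

    @property
    def recombination_nodes(self) -> list[int]:
        return sorted(v for v, ps in self._parents.items() if len(ps) == 2)

    @property
    def is_tree(self) -> bool:
        return len(self.recombination_nodes) == 0 and len(self.roots) == 1

    def roles(self) -> pd.Series:
        out = {}
        for v in self.nodes.index:
            v = int(v)
            nparents = len(self._parents.get(v, ()))
            if self.nodes.at[v, "is_sample"]:
                out[v] = "sample"
            elif nparents == 0:
                out[v] = "root"
            elif nparents == 2:
                out[v] = "recombination"
            elif len(self._children.get(v, ())) >= 2:
                out[v] = "coalescent"
            else:
                out[v] = "common-ancestor"
        return pd.Series(out, name="role").sort_index()

    # ------------------------------------------------------------- accessors

    def node_time(self, v: int) -> float:
        return self._times[int(v)]

    def parents_of(self, v: int) -> list[int]:
        return list(self._parents.get(int(v), ()))

    def children_of(self, v: int) -> list[int]:
        return list(self._children.get(int(v), ()))

    def edge_length(self, child: int, parent: int) -> float:
        return self._edge_len[(int(child), int(parent))]

    def edge_intervals(self, child: int, parent: int) -> list[tuple[float, float]]:
        return list(self._intervals[(int(child), int(parent))])

    def edge_keys(self) -> list[tuple[int, int]]:
        """Distinct (child, parent) pairs; parallel interval rows are merged."""
        return sorted(self._intervals)

    def nodes_by_time(self, reverse: bool = False) -> list[int]:
        return sorted(
            (int(v) for v in self.nodes.index),
            key=lambda v: (self._times[v], v),
            reverse=reverse,
        )

    def breakpoints(self) -> np.ndarray:
        """Genomic breakpoints delimiting the marginal (local) trees."""
        pts = {0.0, self.sequence_length}
        pts.update(float(x) for x in self.edges["left"])
        pts.update(float(x) for x in self.edges["right"])
        return np.array(sorted(p for p in pts if 0.0 <= p <= self.sequence_length))

    def num_trees(self) -> int:
        return max(len(self.breakpoints()) - 1, 1)

    def copy(self) -> "SpatialARG":
        return SpatialARG(
            self.nodes, self.edges, self.locations, self.sequence_length, validate=False
        )

    # ------------------------------------------------------------ restriction

    def restrict(self, left: float, right: float) -> "SpatialARG":
        """Sub-ARG spanned by the genomic interval [left, right).

        Keeps edges overlapping the interval (clipped to it) and all incident
        nodes plus the sample nodes.  Nodes that lose all parent edges become
        roots of the sub-ARG.
        """
        if not (0.0 <= left < right <= self.sequence_length + 1e-9):
            raise ARGError(f"interval [{left}, {right}) outside sequence")
        mask = (self.edges["right"] > left) & (self.edges["left"] < right)
        sub = self.edges.loc[mask].copy()
        sub["left"] = sub["left"].clip(lower=left)
        sub["right"] = sub["right"].clip(upper=right)
        keep = set(sub["parent"]).union(sub["child"]).union(self.sample_ids)
        nodes = self.nodes.loc[sorted(keep)]
        # drop nodes no longer ancestral to any sample within the window
        arg = SpatialARG(nodes, sub, self.locations, self.sequence_length, validate=False)
        anc = arg._sample_ancestral_nodes()
        nodes = nodes.loc[sorted(anc)]
        sub = sub[sub["parent"].isin(anc) & sub["child"].isin(anc)]
        return SpatialARG(nodes, sub, self.locations, self.sequence_length)

    def _sample_ancestral_nodes(self) -> set[int]:
        seen = set(self.sample_ids)
        stack = list(seen)
        while stack:
            v = stack.pop()
            for p in self._parents.get(v, ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    # -------------------------------------------------------------------- IO

    @classmethod
    def from_tables(cls, nodes, edges, locations, sequence_length=None):
        nodes = pd.DataFrame(nodes)
        if "id" in nodes.columns:
            nodes = nodes.set_index("id")
        nodes["is_sample"] = nodes["is_sample"].astype(bool)
        edges = pd.DataFrame(edges)
        locations = pd.DataFrame(locations)
        if "node_id" in locations.columns:
            locations = locations.set_index("node_id")
        return cls(nodes, edges, locations, sequence_length)

    @classmethod
    def from_tskit(cls, ts: tskit.TreeSequence, locations=None):
        """Build from a tree sequence; locations may be a DataFrame/CSV path or
        come from the individual table's ``location`` column."""
        tn = ts.tables.nodes
        nodes = pd.DataFrame(
            {
                "time": np.asarray(tn.time, float),
                "is_sample": (np.asarray(tn.flags) & tskit.NODE_IS_SAMPLE) > 0,
            },
            index=pd.RangeIndex(ts.num_nodes, name="id"),
        )
        te = ts.tables.edges
        edges = pd.DataFrame(
            {
                "parent": np.asarray(te.parent, int),
                "child": np.asarray(te.child, int),
                "left": np.asarray(te.left, float),
                "right": np.asarray(te.right, float),
            }
        )
        if locations is None:
            rows = {}
            for v in ts.samples():
                ind = ts.node(v).individual
                if ind == tskit.NULL:
                    raise ARGError(
                        f"sample node {v} has no individual location; "
                        "provide a location table"
                    )
                loc = ts.individual(ind).location
                rows[int(v)] = loc
            d = len(next(iter(rows.values())))
            cols = ["x", "y"][:d]
            locations = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        elif isinstance(locations, (str, Path)):
            locations = read_locations(locations)
        else:
            locations = pd.DataFrame(locations)
            if "node_id" in locations.columns:
                locations = locations.set_index("node_id")
        return cls(nodes, edges, locations, ts.sequence_length)

    def to_tskit(self) -> tskit.TreeSequence:
        """Export to a tree sequence; sample locations are stored on
        individuals.  Node ids are remapped to 0..n-1 in id order."""
        tables = tskit.TableCollection(sequence_length=self.sequence_length)
        order = sorted(int(v) for v in self.nodes.index)
        remap = {v: i for i, v in enumerate(order)}
        cols = ["x", "y"][: self.ndim]
        for v in order:
            flags = tskit.NODE_IS_SAMPLE if self.nodes.at[v, "is_sample"] else 0
            ind = tskit.NULL
            if self.nodes.at[v, "is_sample"]:
                ind = tables.individuals.add_row(
                    location=self.locations.loc[v, cols].to_numpy(float)
                )
            tables.nodes.add_row(
                flags=flags, time=self.nodes.at[v, "time"], individual=ind
            )
        for row in self.edges.itertuples(index=False):
            tables.edges.add_row(
                left=row.left,
                right=row.right,
                parent=remap[int(row.parent)],
                child=remap[int(row.child)],
            )
        tables.sort()
        return tables.tree_sequence()

    def write_text(self, prefix: str | Path):
        """Write ``<prefix>.nodes.tsv``, ``<prefix>.edges.tsv`` and
        ``<prefix>.locations.csv``."""
        prefix = Path(prefix)
        nodes = self.nodes.reset_index()
        nodes.to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
        self.edges.to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
        self.locations.reset_index().to_csv(
            prefix.with_suffix(".locations.csv"), index=False
        )

    @classmethod
    def read_text(cls, prefix: str | Path):
        prefix = Path(prefix)
        nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
        edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
        locations = pd.read_csv(prefix.with_suffix(".locations.csv"))
        return cls.from_tables(nodes, edges, locations)

    def __repr__(self):
        return (
            f"SpatialARG(nodes={len(self.nodes)}, edges={len(self.edges)}, "
            f"ns={self.ns}, recombination_nodes={len(self.recombination_nodes)}, "
            f"roots={len(self.roots)}, d={self.ndim})"
        )


def read_locations(path) -> pd.DataFrame:
    """Read a sample-location table with columns ``node_id,x[,y]``."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return df.set_index("node_id")


def load_arg(arg_source, locations=None) -> SpatialARG:
    """Load and validate an ARG with sample locations.

    ``arg_source`` may be a .trees file path, a :class:`tskit.TreeSequence`,
    or a text-table prefix (``<prefix>.nodes.tsv`` / ``.edges.tsv``).
    """
    if isinstance(arg_source, tskit.TreeSequence):
        return SpatialARG.from_tskit(arg_source, locations)
    path = Path(arg_source)
    if path.suffix == ".trees":
        return SpatialARG.from_tskit(tskit.load(str(path)), locations)
    nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t")
    edges = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t")
    if locations is None:
        locations = path.with_suffix(".locations.csv")
    if isinstance(locations, (str, Path)):
        locations = read_locations(locations)
    return SpatialARG.from_tables(nodes, edges, locations)


def chop_arg(arg: SpatialARG, cutoff: float) -> SpatialARG:
    """Truncate an ARG at ``cutoff`` generations in the past.

    Edges spanning the cutoff are cut there, each capped by a fresh root node
    at exactly the cutoff time; nodes and edges strictly older are dropped.
    Fresh roots get ids above all existing ids, assigned in ascending order of
    the (child, parent) pair they cap, so output is deterministic.
    """
    if cutoff <= 0:
        raise ARGError("cutoff must be positive")
    max_time = max(
        (arg.node_time(p) for (c, p) in arg.edge_keys()), default=0.0
    )
    if cutoff >= max_time:
        warnings.warn(
            f"cutoff {cutoff} is older than all nodes (GMRCA at {max_time}); "
            "ARG returned unchanged"
        )
        return arg.copy()

    keep_nodes = arg.nodes[arg.nodes["time"] <= cutoff].copy()
    next_id = int(arg.nodes.index.max()) + 1
    new_rows = []
    new_nodes = []
    crossing = sorted(
        (c, p)
        for (c, p) in arg.edge_keys()
        if arg.node_time(c) < cutoff and arg.node_time(p) > cutoff
    )
    for (c, p) in crossing:
        root_id = next_id
        next_id += 1
        new_nodes.append(root_id)
        for (l, r) in arg.edge_intervals(c, p):
            new_rows.append((root_id, c, l, r))
    below = arg.edges[
        arg.edges["parent"].map(arg.nodes["time"]) <= cutoff
    ].copy()
    extra = pd.DataFrame(new_rows, columns=["parent", "child", "left", "right"])
    edges = pd.concat([below, extra], ignore_index=True)
    if new_nodes:
        keep_nodes = pd.concat(
            [
                keep_nodes,
                pd.DataFrame(
                    {"time": cutoff, "is_sample": False},
                    index=pd.Index(new_nodes, name="id"),
                ),
            ]
        )
    out = SpatialARG(keep_nodes, edges, arg.locations, arg.sequence_length,
                     validate=False)
    anc = out._sample_ancestral_nodes()
    nodes = out.nodes.loc[sorted(anc)]
    edges = out.edges[out.edges["parent"].isin(anc) & out.edges["child"].isin(anc)]
    return SpatialARG(nodes, edges, arg.locations, arg.sequence_length)


def find_loops(arg: SpatialARG) -> list[LoopConstraint]:
    """One loop constraint per recombination node whose two parental lineages
    coalesce within the graph.

    Open loops — recombination nodes whose parents reach distinct roots without
    meeting — produce no constraint here (the chop destroyed the loop top);
    they are still conditioned on by the oracle via the path-coincidence
    framing.
    """
    loops = []
    for r in arg.recombination_nodes:
        p1, p2 = arg.parents_of(r)
        anc1 = _ancestor_depths(arg, p1)
        anc2 = _ancestor_depths(arg, p2)
        common = set(anc1) & set(anc2)
        if not common:
            continue
        top = min(common, key=lambda v: (arg.node_time(v), v))
        left = _path_edges(arg, p1, top, anc1) + [(r, p1)]
        right = _path_edges(arg, p2, top, anc2) + [(r, p2)]
        loops.append(LoopConstraint(r, top, left, right))
    return loops


def _ancestor_depths(arg: SpatialARG, v: int) -> dict[int, int | None]:
    """All ancestors of v (inclusive), mapped to a predecessor towards v."""
    pred: dict[int, int | None] = {v: None}
    stack = [v]
    while stack:
        u = stack.pop()
        for p in arg.parents_of(u):
            if p not in pred:
                pred[p] = u
                stack.append(p)
    return pred


def _path_edges(arg, bottom, top, pred) -> list[tuple[int, int]]:
    """Edges from ``top`` down to ``bottom`` following the predecessor map."""
    edges = []
    v = top
    while v != bottom:
        u = pred[v]
        edges.append((u, v))
        v = u
    return edges


def simplify_arg(arg: SpatialARG) -> SpatialARG:
    """Remove pass-through chains: nodes with exactly one distinct child and
    one distinct parent are deleted and their child re-attached to their
    parent on the intersected genome intervals.

    Coalescent nodes, recombination nodes, samples and roots are retained.
    Applied repeatedly until stable (merging two parallel edges can make a
    former recombination node unary).
    """
    edges = {k: list(v) for k, v in arg._intervals.items()}
    samples = set(arg.sample_ids)
    changed = True
    while changed:
        changed = False
        parents: dict[int, set[int]] = {}
        children: dict[int, set[int]] = {}
        for (c, p) in edges:
            parents.setdefault(c, set()).add(p)
            children.setdefault(p, set()).add(c)
        for v in sorted(parents, key=lambda u: arg.node_time(u)):
            if v in samples:
                continue
            ps = parents.get(v, set())
            cs = children.get(v, set())
            if len(ps) == 1 and len(cs) == 1:
                (p,), (c,) = ps, cs
                if p == c:
                    continue
                up = edges.pop((v, p))
                down = edges.pop((c, v))
                merged = _intersect_intervals(down, up)
                if merged:
                    edges.setdefault((c, p), []).extend(merged)
                    edges[(c, p)] = _merge_adjacent(edges[(c, p)])
                changed = True
                parents.get(c, set()).discard(v)
                parents.setdefault(c, set()).add(p)
                children.get(p, set()).discard(v)
                children.setdefault(p, set()).add(c)
                parents.pop(v, None)
                children.pop(v, None)
    rows = [
        (p, c, l, r) for (c, p), ivs in edges.items() for (l, r) in ivs
    ]
    edf = pd.DataFrame(rows, columns=["parent", "child", "left", "right"])
    keep = set(edf["parent"]).union(edf["child"]).union(samples)
    return SpatialARG(
        arg.nodes.loc[sorted(keep)], edf, arg.locations, arg.sequence_length
    )


def _intersect_intervals(a, b):
    out = []
    for (l1, r1) in a:
        for (l2, r2) in b:
            l, r = max(l1, l2), min(r1, r2)
            if r > l:
                out.append((l, r))
    return _merge_adjacent(out)


def _merge_adjacent(ivs):
    ivs = sorted(ivs)
    out = []
    for (l, r) in ivs:
        if out and l <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], r))
        else:
            out.append((l, r))
    return out
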