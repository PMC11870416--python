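"""Model variant and baseline estimators.

Three points of comparison for the main (meeting-constrained) ARG model:

* the *midpoint* variant, which lets the two parents of a recombination node
  be any distance apart and places the node at their unweighted average —
  sample covariances come from propagating averaging weights down the graph;
* the per-tree *composite likelihood*: single-tree Brownian fits averaged
  over marginal trees;
* *averaging-up*: each node located at the plain mean of its children's
  locations, branch lengths ignored, computed on the simplified ARG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arg import SpatialARG, chop_arg, simplify_arg
from .estimate import FitResult, _fit_from_matrices, restrict_to_trees

__all__ = [
    "midpoint_shared_times",
    "midpoint_node_variances",
    "midpoint_fit",
    "tree_composite_fit",
    "averaging_up",
]


def _edge_weights(arg: SpatialARG):
    """Per-node weight vectors over edge displacements and roots under the
    midpoint model: a recombination node's location is the average of its two
    parents' endpoints; all weights are ½–½ per parent pair."""
    roots = arg.roots
    ridx = {r: i for i, r in enumerate(roots)}
    w_edges: dict[int, dict] = {}
    w_roots: dict[int, np.ndarray] = {}
    for v in arg.nodes_by_time(reverse=True):
        parents = arg.parents_of(v)
        if not parents:
            w_edges[v] = {}
            wr = np.zeros(len(roots))
            wr[ridx[v]] = 1.0
            w_roots[v] = wr
            continue
        share = 1.0 / len(parents)
        we: dict = {}
        wr = np.zeros(len(roots))
        for p in parents:
            for e, wt in w_edges[p].items():
                we[e] = we.get(e, 0.0) + share * wt
            we[(v, p)] = we.get((v, p), 0.0) + share
            wr += share * w_roots[p]
        w_edges[v] = we
        w_roots[v] = wr
    return w_edges, w_roots, roots


def midpoint_shared_times(arg: SpatialARG):
    """Sample-location covariance structure under the midpoint model.

    Returns ``(C, P, R)`` shaped like the main model's ``(Sp, P, R)``:
    ``σ²C`` is the sample covariance, ``P`` is the identity (one "path" per
    sample) and ``R`` holds each sample's root weights, so the generic GLS
    machinery applies unchanged.  For a tree this reduces exactly to the
    main-model shared-time matrix.
    """
    w_edges, w_roots, roots = _edge_weights(arg)
    sids = arg.sample_ids
    ns = len(sids)
    C = np.zeros((ns, ns))
    for i, si in enumerate(sids):
        wi = w_edges[si]
        for j in range(i, ns):
            wj = w_edges[sids[j]]
            small, big = (wi, wj) if len(wi) <= len(wj) else (wj, wi)
            v = sum(
                wt * big[e] * arg.edge_length(*e)
                for e, wt in small.items()
                if e in big
            )
            C[i, j] = C[j, i] = v
    P = np.eye(ns)
    R = np.array([w_roots[s] for s in sids])
    return C, P, R


def midpoint_node_variances(arg: SpatialARG) -> pd.Series:
    """Unconditional variance factor of every node's location under the
    midpoint model (multiply by σ²)."""
    w_edges, _, _ = _edge_weights(arg)
    return pd.Series(
        {
            int(v): sum(wt**2 * arg.edge_length(*e) for e, wt in w_edges[int(v)].items())
            for v in arg.nodes.index
        },
        name="variance_factor",
    ).sort_index()


def midpoint_fit(
    arg: SpatialARG, cutoff: float | None = None, denominator: str = "mle"
) -> FitResult:
    """Root-location and dispersal MLEs under the midpoint model."""
    if cutoff is not None:
        arg = chop_arg(arg, cutoff)
    C, P, R = midpoint_shared_times(arg)
    res = _fit_from_matrices(C, P, R, arg.locations_array, arg.roots, denominator)
    res.arg = arg
    return res


@dataclass
class CompositeFit:
    """Per-marginal-tree fits plus the running composite average."""

    tree_fits: list[FitResult]
    breakpoints: np.ndarray

    @property
    def sigma2_per_tree(self) -> np.ndarray:
        return np.array([f.sigma2_scalar for f in self.tree_fits])

    @property
    def running_average(self) -> np.ndarray:
        s = self.sigma2_per_tree
        return np.cumsum(s) / np.arange(1, len(s) + 1)

    @property
    def average_sigma2(self) -> float:
        return float(self.sigma2_per_tree.mean())


def tree_composite_fit(
    arg: SpatialARG, cutoff: float | None = None, max_trees: int | None = None
) -> CompositeFit:
    """Single-tree Brownian-motion fit on each marginal tree, plus the
    running average dispersal estimate over trees (the composite-likelihood
    baseline, no importance sampling)."""
    from .estimate import fit as _fit

    bp = arg.breakpoints()
    ntrees = len(bp) - 1
    if max_trees is not None:
        ntrees = min(ntrees, max_trees)
    fits = []
    for k in range(ntrees):
        sub = restrict_to_trees(arg, k, k)
        fits.append(_fit(sub, cutoff))
    return CompositeFit(fits, bp[: ntrees + 1])


def averaging_up(arg: SpatialARG, simplify: bool = True) -> pd.DataFrame:
    """Locate every internal node at the unweighted mean of its children's
    locations (branch lengths ignored), in one tip-to-root pass over the
    simplified ARG.  Nodes with a single child copy the child's value."""
    if simplify:
        arg = simplify_arg(arg)
    cols = ["x", "y"][: arg.ndim]
    locs: dict[int, np.ndarray] = {
        s: arg.locations.loc[s, cols].to_numpy(float) for s in arg.sample_ids
    }
    for v in arg.nodes_by_time():
        if v in locs:
            continue
        kids = arg.children_of(v)
        if not kids:
            continue
        locs[v] = np.mean([locs[c] for c in kids], axis=0)
    return pd.DataFrame.from_dict(locs, orient="index", columns=cols).sort_index()
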