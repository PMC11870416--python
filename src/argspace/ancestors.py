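"""Conditional location distributions of genetic ancestors.

Given the fitted (or true) dispersal rate and root locations, the location of
any internal node — or of a point part-way along an edge — is Gaussian with

    mean     = μ̂_ra + saᵀ Sp⁻ (Pℓ* − Rμ̂)
    variance = σ̂² · V,   V = (ta − saᵀ Sp⁻ sa)
                           + (e_ra − Rᵀ Sp⁻ sa)ᵀ (Rᵀ Sp⁻ R)⁻¹ (e_ra − Rᵀ Sp⁻ sa)

where ``sa`` holds the shared times between one (arbitrary, deterministic)
node-to-root path and the minimal sample paths, ``ta`` is the node's time to
its root, and the two terms of V are the Brownian-motion and root-uncertainty
components.  Dispersal-estimation uncertainty is not propagated into V: σ̂²
and μ̂ enter as plug-ins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arg import ARGError, SpatialARG
from .estimate import FitResult
from .likelihood import generalized_inverse
from .paths import PathSet, ancestor_shared_times, canonical_path, _path_edge_sets

__all__ = [
    "AncestorLocation",
    "ancestor_mean",
    "ancestor_variance",
    "locate_ancestor",
    "confidence_region",
]


@dataclass
class AncestorLocation:
    """Location distribution of one genetic ancestor."""

    node: int | None
    time: float
    mean: np.ndarray            # length-d
    V: float                    # variance factor (× σ² gives the variance)
    bm_component: float
    root_component: float
    sigma2: np.ndarray          # d × d plug-in dispersal
    level: float = 0.95

    @property
    def total_variance(self) -> np.ndarray:
        """σ̂²·V (d=1: 1×1; d=2: 2×2 = Σ̂·V)."""
        return self.sigma2 * self.V

    def to_dict(self) -> dict:
        return {
            "node": None if self.node is None else int(self.node),
            "time": float(self.time),
            "mean": np.asarray(self.mean).tolist(),
            "V": float(self.V),
            "bm_component": float(self.bm_component),
            "root_component": float(self.root_component),
            "total_variance": np.asarray(self.total_variance).tolist(),
            "level": self.level,
        }


def ancestor_mean(sa, ta, root_index, Sp, P, R, locations, mu_hat, rtol=None):
    """Conditional mean of the ancestor's location (independent per
    dimension)."""
    loc = np.atleast_2d(np.asarray(locations, float))
    if loc.shape[0] == 1 and P.shape[1] != 1:
        loc = loc.T
    mu = np.atleast_2d(np.asarray(mu_hat, float))
    if mu.shape[0] == 1 and R.shape[1] != 1:
        mu = mu.T
    Spg = generalized_inverse(Sp, rtol)
    resid = P @ loc - R @ mu
    return mu[root_index] + np.asarray(sa, float) @ Spg @ resid


def ancestor_variance(sa, ta, root_index, Sp, R, rtol=None):
    """Variance factor V and its Brownian-motion / root-uncertainty split."""
    sa = np.asarray(sa, float)
    Spg = generalized_inverse(Sp, rtol)
    bm = float(ta - sa @ Spg @ sa)
    if bm < -1e-8 * max(ta, 1.0):
        raise ARGError(
            f"negative Brownian variance component ({bm}); sa is inconsistent "
            "with the path basis"
        )
    bm = max(bm, 0.0)
    e = np.zeros(R.shape[1])
    e[root_index] = 1.0
    u = e - R.T @ Spg @ sa
    A = R.T @ Spg @ R
    root = float(u @ np.linalg.pinv(A) @ u)
    root = max(root, 0.0)
    return bm + root, bm, root


def _edge_at(arg: SpatialARG, sample: int, position: float, time: float):
    """Walk the sample's lineage at a genome position up to ``time``.

    Returns ``(node, None)`` if the lineage sits exactly at a node then, else
    ``(child, parent)`` for the edge spanning that time.
    """
    if not 0.0 <= position < arg.sequence_length:
        raise ARGError(f"position {position} outside sequence")
    v = int(sample)
    if time < arg.node_time(v):
        raise ARGError(f"time {time} predates sample {sample}")
    while True:
        if arg.node_time(v) == time:
            return v, None
        nxt = None
        for p in arg.parents_of(v):
            if any(l <= position < r for (l, r) in arg.edge_intervals(v, p)):
                nxt = p
                break
        if nxt is None:
            raise ARGError(
                f"lineage of sample {sample} at position {position} ends at "
                f"time {arg.node_time(v)}, above which no edge exists "
                f"(requested time {time})"
            )
        if arg.node_time(nxt) > time:
            return v, nxt
        v = nxt


def _point_shared_times(arg, paths: PathSet, child, parent, tau):
    """sa/ta for a point at time ``tau`` on the edge child→parent: the point's
    path continues from ``parent`` along its canonical path; shared time with
    any sample path containing this edge accrues linearly along the edge."""
    up = canonical_path(arg, parent)
    root = up[-1]
    ta = arg.node_time(root) - tau
    a_edges = {(up[i], up[i + 1]) for i in range(len(up) - 1)}
    partial = (int(child), int(parent))
    sa = np.zeros(paths.np_)
    for i, es in enumerate(_path_edge_sets(paths.paths)):
        sa[i] = sum(arg.edge_length(*e) for e in (a_edges & es))
        if partial in es:
            sa[i] += arg.node_time(parent) - tau
    return sa, ta, paths.root_ids.index(root)


def locate_ancestor(
    arg: SpatialARG,
    sample: int,
    position: float,
    time: float,
    fit: FitResult,
    level: float = 0.95,
    sigma2=None,
) -> AncestorLocation:
    """Location distribution of the ancestor of ``sample`` at a genome
    position and time.

    The unique edge of the local tree at ``position`` carrying the sample's
    lineage at ``time`` is identified; both the node case and the mid-edge
    case are supported.  ``fit`` supplies the matrices and plug-in estimates
    (``sigma2`` overrides the fitted dispersal rate, e.g. to use the truth).
    """
    if fit.arg is None or fit.path_set is None or fit.Sp is None:
        raise ValueError("fit must carry its ARG and path matrices (use fit())")
    farg = fit.arg
    ps = fit.path_set
    node, parent = _edge_at(farg, sample, position, time)
    if parent is None:
        sa, ta, ridx = ancestor_shared_times(farg, node, ps)
        out_node = node
    else:
        sa, ta, ridx = _point_shared_times(farg, ps, node, parent, time)
        out_node = None
    loc = farg.locations_array
    mean = ancestor_mean(sa, ta, ridx, fit.Sp, ps.P, ps.R, loc, fit.mu_hat)
    V, bm, root = ancestor_variance(sa, ta, ridx, fit.Sp, ps.R)
    s2 = np.atleast_2d(np.asarray(fit.sigma2_hat if sigma2 is None else sigma2, float))
    return AncestorLocation(
        node=out_node,
        time=float(time),
        mean=np.asarray(mean, float).ravel(),
        V=V,
        bm_component=bm,
        root_component=root,
        sigma2=s2,
        level=level,
    )


def confidence_region(loc: AncestorLocation, level: float | None = None):
    """Central Gaussian confidence interval (d=1) or ellipse (d=2).

    d=1: returns ``(lo, hi)``.  d=2: returns a dict with the ellipse centre,
    semi-axes and orientation at the given level.
    """
    level = loc.level if level is None else level
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cov = np.atleast_2d(loc.total_variance)
    d = cov.shape[0]
    if d == 1:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(cov[0, 0], 0.0))
        m = float(loc.mean[0])
        return (m - half, m + half)
    w, U = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    chi2 = stats.chi2.ppf(level, df=2)
    return {
        "center": np.asarray(loc.mean, float),
        "semi_axes": np.sqrt(chi2 * w),
        "angle": float(np.arctan2(U[1, -1], U[0, -1])),
        "level": level,
    }
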