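"""Closed-form MLEs of root locations and dispersal rate, with fit drivers.

Root locations are generalized-least-squares estimates on the path matrix,

    μ̂ = (Rᵀ Sp⁻ R)⁻¹ Rᵀ Sp⁻ P ℓ*,

and the dispersal rate is the residual quadratic form divided by the number
of samples,

    σ̂² = (Pℓ* − Rμ̂)ᵀ Sp⁻ (Pℓ* − Rμ̂) / ns,

the maximum-likelihood estimator (an optional REML-style ns − nr denominator
is available).  In 2D the residual cross-products give the 2×2 matrix Σ̂.
``fit`` chains chop → minimal paths → shared times → MLEs → log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .arg import SpatialARG, chop_arg
from .likelihood import generalized_inverse, log_likelihood
from .paths import PathSet, SharedTimeMatrix, minimal_paths, shared_times

__all__ = [
    "FitResult",
    "mle_root_locations",
    "mle_dispersal",
    "fit",
    "windowed_fit",
    "restrict_to_trees",
]


@dataclass
class FitResult:
    """MLEs and diagnostics from one ARG fit."""

    mu_hat: np.ndarray          # nr × d
    sigma2_hat: np.ndarray      # () scalar for d=1, 2×2 for d=2
    loglik: float
    ns: int
    np_: int
    nr: int
    root_ids: list[int]
    ndim: int
    diagnostics: dict[str, Any] = field(default_factory=dict)
    arg: SpatialARG | None = None
    path_set: PathSet | None = None
    Sp: np.ndarray | None = None

    @property
    def sigma2_scalar(self) -> float:
        """Mean per-dimension dispersal rate (σ² for d=1, tr(Σ̂)/2 for d=2)."""
        s = np.atleast_2d(self.sigma2_hat)
        return float(np.trace(s) / s.shape[0])

    def to_dict(self) -> dict:
        return {
            "mu_hat": np.asarray(self.mu_hat).tolist(),
            "sigma2_hat": np.asarray(self.sigma2_hat).tolist(),
            "loglik": self.loglik,
            "ns": self.ns,
            "np": self.np_,
            "nr": self.nr,
            "root_ids": [int(r) for r in self.root_ids],
            "ndim": self.ndim,
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


def mle_root_locations(Sp, P, R, locations, rtol=None):
    """GLS estimate of the root locations (nr × d)."""
    loc = np.atleast_2d(np.asarray(locations, float))
    if loc.shape[0] == 1 and P.shape[1] != 1:
        loc = loc.T
    Spg = generalized_inverse(Sp, rtol)
    A = R.T @ Spg @ R
    b = R.T @ Spg @ P @ loc
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[0]:
        warnings.warn(
            "Rᵀ Sp⁻ R is rank deficient; some root locations are not "
            "identifiable — returning the minimum-norm solution"
        )
        return np.linalg.pinv(A) @ b
    return np.linalg.solve(A, b)


def mle_dispersal(Sp, P, R, locations, mu_hat, rtol=None, denominator="mle"):
    """Dispersal-rate MLE: residual quadratic form over ns (or ns − nr for
    the REML-style correction).  Returns a d × d matrix (1×1 for d = 1)."""
    loc = np.atleast_2d(np.asarray(locations, float))
    if loc.shape[0] == 1 and P.shape[1] != 1:
        loc = loc.T
    mu = np.atleast_2d(np.asarray(mu_hat, float))
    if mu.shape[0] == 1 and R.shape[1] != 1:
        mu = mu.T
    Spg = generalized_inverse(Sp, rtol)
    X = P @ loc - R @ mu
    Q = X.T @ Spg @ X
    ns = P.shape[1]
    nr = R.shape[1]
    if denominator == "mle":
        den = ns
    elif denominator == "reml":
        den = ns - nr
        if den <= 0:
            raise ValueError("ns - nr must be positive for the REML denominator")
    else:
        raise ValueError("denominator must be 'mle' or 'reml'")
    return Q / den


def _fit_from_matrices(Sp, P, R, locations, root_ids, denominator="mle", rtol=None):
    mu_hat = mle_root_locations(Sp, P, R, locations, rtol)
    sig = mle_dispersal(Sp, P, R, locations, mu_hat, rtol, denominator)
    sigma2 = sig if sig.shape == (2, 2) else sig.reshape(())
    sig_eval = float(sig[0, 0]) if sig.shape != (2, 2) else sig
    ll = log_likelihood(Sp, P, R, locations, mu_hat, sig_eval, rtol)
    w = np.linalg.eigvalsh(Sp)
    diagnostics = {
        "Sp_condition": float(w.max() / max(w.min(), 1e-300)) if len(w) else np.nan,
        "Sp_rank": int(np.sum(w > 1e-10 * max(w.max(), 1e-300))),
    }
    return FitResult(
        mu_hat=mu_hat,
        sigma2_hat=sigma2,
        loglik=ll,
        ns=P.shape[1],
        np_=P.shape[0],
        nr=R.shape[1],
        root_ids=list(root_ids),
        ndim=1 if sig.shape != (2, 2) else 2,
        diagnostics=diagnostics,
    )


def fit(
    arg: SpatialARG,
    cutoff: float | None = None,
    denominator: str = "mle",
    rtol: float | None = None,
) -> FitResult:
    """Whole-ARG fit: chop (optional) → minimal paths → shared times →
    root-location and dispersal MLEs → log-likelihood."""
    if cutoff is not None:
        arg = chop_arg(arg, cutoff)
    ps = minimal_paths(arg)
    stm = shared_times(arg, ps)
    loc = arg.locations_array
    res = _fit_from_matrices(stm.Sp, ps.P, ps.R, loc, ps.root_ids, denominator, rtol)
    res.arg = arg
    res.path_set = ps
    res.Sp = stm.Sp
    nrec = len(arg.recombination_nodes)
    res.diagnostics["n_recombination_nodes"] = nrec
    if nrec:
        from .arg import find_loops

        closed = len(find_loops(arg))
        # loops destroyed by the chop (parents reach distinct roots) change
        # the degrees of freedom absorbed by root estimation
        res.diagnostics["n_open_loops"] = nrec - closed
    return res


def restrict_to_trees(arg: SpatialARG, first: int, last: int) -> SpatialARG:
    """Sub-ARG spanned by marginal trees ``first..last`` (inclusive,
    0-based)."""
    bp = arg.breakpoints()
    ntrees = len(bp) - 1
    first = max(0, first)
    last = min(ntrees - 1, last)
    if first > last:
        raise ValueError("empty tree range")
    return arg.restrict(bp[first], bp[last + 1])


def windowed_fit(
    arg: SpatialARG,
    focal_tree_index: int,
    half_width_trees: int,
    cutoff: float | None = None,
    denominator: str = "mle",
    rechop: bool = True,
) -> FitResult:
    """Fit on the local ARG of ``2·half_width+1`` trees centred on the focal
    tree (fewer at chromosome ends).  The sub-ARG is re-chopped at ``cutoff``
    by default."""
    ntrees = arg.num_trees()
    if not 0 <= focal_tree_index < ntrees:
        raise ValueError(f"focal tree {focal_tree_index} outside 0..{ntrees - 1}")
    sub = restrict_to_trees(
        arg, focal_tree_index - half_width_trees, focal_tree_index + half_width_trees
    )
    return fit(sub, cutoff if rechop else None, denominator)
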