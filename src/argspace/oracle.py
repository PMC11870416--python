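"""Exact, slow reference computations for the fast path-matrix machinery.

Every node location in an ARG is a linear function of independent edge
displacements plus a root constant.  This module builds that representation
explicitly (recombination nodes get a left and a right copy, one per parent
edge), conditions exactly on the meeting constraints — left copy equals right
copy at every recombination node — by linear-Gaussian conditioning in
displacement space, and exposes conditional means/variances of any node given
the sample locations.  It is dense and O(n³); it exists for correctness, not
speed, and is the ground truth the path-matrix results are tested against.
"""

from __future__ import annotations

import numpy as np

from .arg import SpatialARG

__all__ = ["JointGaussian", "build_joint", "condition_on_loops", "bridge_variance"]


def _pinvh(M, rtol=1e-11):
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    cut = rtol * max(np.abs(w).max(), np.finfo(float).tiny) * M.shape[0]
    inv = np.where(np.abs(w) > cut, 1.0 / np.where(np.abs(w) > cut, w, 1.0), 0.0)
    return (U * inv) @ U.T


class JointGaussian:
    """Joint Gaussian of all node-copy locations as linear maps of edge
    displacements.

    Attributes
    ----------
    var_names:
        One entry per variable: a node id for each node (its left copy) plus
        ``("right", r)`` for each recombination node r.
    M, W:
        nvars × nr root-indicator matrix and nvars × nedges weight matrix:
        location = M μ + W ξ with ξ the vector of edge displacements,
        ξ ~ N(0, σ² diag(lengths)) before conditioning.
    A, B:
        Constraint rows: A ξ + B μ = 0 encodes "left copy = right copy" at
        every recombination node (B is nonzero only for loop-open cases where
        the two parents trace to different roots).
    """

    def __init__(self, arg: SpatialARG, mu, sigma2, max_vars: int = 200):
        self.arg = arg
        self.root_ids = arg.roots
        nr = len(self.root_ids)
        mu = np.asarray(mu, float)
        if mu.ndim == 1:
            mu = mu.reshape(nr, 1) if mu.size == nr else mu.reshape(nr, -1)
        if mu.shape[0] != nr:
            raise ValueError(f"mu must have one row per root ({nr})")
        self.mu = mu
        self.sigma2 = np.atleast_2d(np.asarray(sigma2, float))
        self.edge_keys = arg.edge_keys()
        self.lengths = np.array([arg.edge_length(c, p) for (c, p) in self.edge_keys])
        eidx = {e: i for i, e in enumerate(self.edge_keys)}
        ridx = {r: i for i, r in enumerate(self.root_ids)}
        rec = set(arg.recombination_nodes)
        nvars = len(arg.nodes) + len(rec)
        if nvars > max_vars:
            raise ValueError(
                f"{nvars} node copies exceeds the oracle cap ({max_vars}); "
                "the oracle is for small reference problems"
            )
        ne = len(self.edge_keys)
        self.var_names: list = []
        self._vrow: dict = {}
        rows_M, rows_W = [], []
        cons_A, cons_B = [], []
        order = arg.nodes_by_time(reverse=True)
        for v in order:
            parents = arg.parents_of(v)
            m = np.zeros(nr)
            w = np.zeros(ne)
            if not parents:
                m[ridx[v]] = 1.0
            else:
                p0 = parents[0]
                m = rows_M[self._vrow[p0]].copy()
                w = rows_W[self._vrow[p0]].copy()
                w[eidx[(v, p0)]] += 1.0
            self._vrow[v] = len(self.var_names)
            self.var_names.append(v)
            rows_M.append(m)
            rows_W.append(w)
            if len(parents) == 2:
                p1 = parents[1]
                m2 = rows_M[self._vrow[p1]].copy()
                w2 = rows_W[self._vrow[p1]].copy()
                w2[eidx[(v, p1)]] += 1.0
                self._vrow[("right", v)] = len(self.var_names)
                self.var_names.append(("right", v))
                rows_M.append(m2)
                rows_W.append(w2)
                cons_A.append(w - w2)
                cons_B.append(m - m2)
        self.M = np.array(rows_M)
        self.W = np.array(rows_W)
        self.A = np.array(cons_A) if cons_A else np.zeros((0, ne))
        self.B = np.array(cons_B) if cons_B else np.zeros((0, nr))
        self.conditioned = False
        self.Dc = np.diag(self.lengths)
        self.G = np.zeros((ne, nr))

    # ------------------------------------------------------------ conditioning

    def condition_on_loops(self) -> "JointGaussian":
        """Exact conditional law given all left-copy = right-copy equalities."""
        out = self.copy()
        out._apply_constraints(self.A, self.B)
        out.conditioned = True
        return out

    def condition_on_constraints(self, A, B=None) -> "JointGaussian":
        """Condition on arbitrary linear constraints ``A ξ + B μ = 0`` in
        displacement space (used e.g. to impose path-tip coincidence
        directly)."""
        out = self.copy()
        if B is None:
            B = np.zeros((A.shape[0], len(self.root_ids)))
        out._apply_constraints(np.asarray(A, float), np.asarray(B, float))
        out.conditioned = True
        return out

    def _apply_constraints(self, A, B):
        if A.shape[0] == 0:
            return
        D = self.Dc
        S = A @ D @ A.T
        Sg = _pinvh(S)
        # consistency: B μ must lie in the range of A D Aᵀ shifted space
        DAt = D @ A.T
        self.Dc = D - DAt @ Sg @ DAt.T
        self.G = self.G - DAt @ Sg @ (A @ self.G + B)

    def copy(self) -> "JointGaussian":
        out = object.__new__(JointGaussian)
        out.__dict__.update(self.__dict__)
        out.Dc = self.Dc.copy()
        out.G = self.G.copy()
        return out

    # --------------------------------------------------------------- queries

    @property
    def M_eff(self) -> np.ndarray:
        """Effective root-to-variable map after conditioning (M + W G)."""
        return self.M + self.W @ self.G

    def var_index(self, name) -> int:
        return self._vrow[name]

    def mean(self) -> np.ndarray:
        """nvars × d mean vector."""
        return self.M_eff @ self.mu

    def structural_cov(self, rows=None) -> np.ndarray:
        """Covariance / σ² between variables (all, or the given var names)."""
        W = self.W if rows is None else self.W[[self._vrow[r] for r in rows]]
        return W @ self.Dc @ W.T

    def sample_cov(self) -> np.ndarray:
        """Structural covariance of the sample locations (× σ² for the real
        covariance); after conditioning this is the sample matrix S."""
        return self.structural_cov(self.arg.sample_ids)

    def sample(self, rng: np.random.Generator) -> dict[int, np.ndarray]:
        """Draw one realization of every node location (d-dim each)."""
        d = self.mu.shape[1]
        w, U = np.linalg.eigh(0.5 * (self.Dc + self.Dc.T))
        w = np.clip(w, 0.0, None)
        Aroot = U * np.sqrt(w)
        Z = rng.standard_normal((len(self.lengths), d))
        if d == 2:
            Ls = np.linalg.cholesky(self.sigma2)
            xi = Aroot @ Z @ Ls.T
        else:
            xi = Aroot @ Z * np.sqrt(self.sigma2[0, 0])
        xi = xi + self.G @ self.mu
        vals = self.M @ self.mu + self.W @ xi
        return {
            v: vals[self._vrow[v]]
            for v in self.arg.nodes.index.astype(int)
        }

    def conditional_ancestor(
        self, node, sample_locations=None, root_prior: str = "fixed"
    ):
        """Exact conditional of one node's location given the sample locations.

        With ``root_prior='fixed'`` the roots are pinned at their known μ;
        with ``'flat'`` the root locations carry an improper uniform prior and
        are integrated out (the regime of the path-matrix plug-in formulas).
        Returns ``(mean, V)``: the d-vector conditional mean and the
        *structural* variance factor (multiply by σ² or Σ).
        """
        sids = self.arg.sample_ids
        y = (
            np.array([self._loc_row(s) for s in sids])
            if sample_locations is None
            else np.atleast_2d(np.asarray(sample_locations, float))
        )
        if y.shape[0] != len(sids):
            y = y.T
        rows = [node] + sids
        V = self.structural_cov(rows)
        Me = self.M_eff[[self._vrow[r] for r in rows]]
        Vaa, Vas, Vss = V[0, 0], V[0:1, 1:], V[1:, 1:]
        Ma, Ms = Me[0:1], Me[1:]
        Vssg = _pinvh(Vss)
        H = Vas @ Vssg  # 1 × ns
        v_fixed = float(Vaa - (H @ Vas.T)[0, 0])
        if root_prior == "fixed":
            mean = (Ma @ self.mu + H @ (y - Ms @ self.mu)).ravel()
            return mean, max(v_fixed, 0.0)
        if root_prior != "flat":
            raise ValueError("root_prior must be 'fixed' or 'flat'")
        F = Ms.T @ Vssg @ Ms
        Fg = _pinvh(F)
        mu_hat = Fg @ Ms.T @ Vssg @ y
        g = Ma - H @ Ms  # 1 × nr
        mean = (g @ mu_hat + H @ y).ravel()
        v = v_fixed + float((g @ Fg @ g.T)[0, 0])
        return mean, max(v, 0.0)

    def _loc_row(self, s):
        return self.arg.locations.loc[s, ["x", "y"][: self.arg.ndim]].to_numpy(float)


def build_joint(arg: SpatialARG, mu, sigma2, max_vars: int = 200) -> JointGaussian:
    """Unconstrained forward model: each node copy is its parent's location
    plus an independent N(0, σ²·edge length) displacement; roots fixed at μ."""
    return JointGaussian(arg, mu, sigma2, max_vars)


def condition_on_loops(jg: JointGaussian) -> JointGaussian:
    return jg.condition_on_loops()


def bridge_variance(total_loop_time: float, t_x: float) -> float:
    """Brownian-bridge variance factor at time ``t_x`` from the top of a loop
    of total time ``total_loop_time`` (multiply by σ²).  At the recombination
    node of a symmetric loop (t_x = total/2) this is total/4 = t/2."""
    if not 0.0 <= t_x <= total_loop_time:
        raise ValueError("t_x must lie within [0, total_loop_time]")
    if total_loop_time == 0:
        return 0.0
    return t_x * (total_loop_time - t_x) / total_loop_time
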