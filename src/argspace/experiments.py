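"""Reusable validation experiments.

Desk-scale versions of the headline simulation studies: confidence-interval
calibration on model-exact data, and the tree-count dispersal-bias experiment
on individual-based data.  Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ancestors import ancestor_mean, ancestor_variance
from .arg import SpatialARG
from .baselines import midpoint_fit, tree_composite_fit
from .estimate import fit, restrict_to_trees
from .likelihood import ModelSpec
from .paths import ancestor_shared_times, minimal_paths, shared_times
from .simulate import IBDParams, simulate_ibd, simulate_locations, simulate_model_arg
from .estimate import mle_root_locations

__all__ = ["coverage_experiment", "bias_experiment", "BiasResult"]


def coverage_experiment(
    n_args: int = 200,
    level: float = 0.95,
    sigma2: float = 1.0,
    seed: int = 1,
    ns_range: tuple[int, int] = (5, 20),
    loops_range: tuple[int, int] = (0, 4),
) -> dict:
    """Empirical coverage of nominal ancestor confidence intervals.

    For each replicate a random ARG topology is generated, every node's
    location is drawn exactly from the loop-conditioned Brownian model with
    known dispersal rate and root locations, and each internal (non-sample,
    non-root) node's central interval at ``level`` — built from the *true*
    σ² but estimated root locations — is checked against the node's true
    simulated location.
    """
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(0.5 + level / 2.0)
    hits = 0
    total = 0
    for i in range(n_args):
        topo_seed = int(rng.integers(1, 2**31 - 1))
        ns = int(rng.integers(ns_range[0], ns_range[1] + 1))
        target = float(rng.integers(loops_range[0], loops_range[1] + 1))
        arg = simulate_model_arg(ns=ns, target_recombinations=target,
                                 seed=topo_seed)
        nr = len(arg.roots)
        model = ModelSpec(mu=np.zeros((nr, 1)), sigma2=sigma2)
        locs = simulate_locations(arg, model, "meeting",
                                  seed=int(rng.integers(1, 2**31 - 1)))
        y = locs.loc[arg.sample_ids].to_numpy()
        ps = minimal_paths(arg)
        Sp = shared_times(arg, ps).Sp
        mu_hat = mle_root_locations(Sp, ps.P, ps.R, y)
        internal = [
            int(v)
            for v in arg.nodes.index
            if int(v) not in set(arg.sample_ids) and int(v) not in set(arg.roots)
        ]
        for v in internal:
            sa, ta, ridx = ancestor_shared_times(arg, v, ps)
            mean = float(
                ancestor_mean(sa, ta, ridx, Sp, ps.P, ps.R, y, mu_hat)[0]
            )
            V, _, _ = ancestor_variance(sa, ta, ridx, Sp, ps.R)
            half = z * np.sqrt(sigma2 * V)
            truth = float(locs.loc[v].iloc[0])
            hits += mean - half <= truth <= mean + half
            total += 1
    return {"coverage": hits / total, "n_draws": total, "level": level,
            "n_args": n_args}


@dataclass
class BiasResult:
    """Dispersal estimates as a function of the number of trees included."""

    ks: list[int]
    arg_sigma2: list[list[float]]       # per replicate, per k
    midpoint_sigma2: list[list[float]]
    composite_running: list[list[float]]  # running average at each k
    realized: list[float]
    effective: float

    def trends(self):
        """Mean Spearman rank correlation of each estimate with k."""
        def rho(series):
            return float(
                np.mean([stats.spearmanr(self.ks, v).statistic for v in series])
            )

        return {
            "arg": rho(self.arg_sigma2),
            "midpoint": rho(self.midpoint_sigma2),
            "composite": rho(self.composite_running),
        }

    def slopes(self):
        """Mean least-squares slope (per tree) of each estimate vs k."""
        ks = np.asarray(self.ks, float)

        def slope(series):
            return float(
                np.mean([np.polyfit(ks, v, 1)[0] for v in series])
            )

        return {
            "arg": slope(self.arg_sigma2),
            "midpoint": slope(self.midpoint_sigma2),
            "composite": slope(self.composite_running),
        }


def bias_experiment(
    replicates: int = 3,
    seed: int = 1,
    n_ks: int = 6,
    params: IBDParams | None = None,
) -> BiasResult:
    """Dispersal-rate estimates vs number of trees on individual-based data.

    Reproduces the qualitative pattern of the ARG likelihood (estimate grows
    with the number of trees), the per-tree composite average (stabilizes)
    and the midpoint variant (grows more slowly), at desk scale.
    """
    base = params or IBDParams(
        n0=150, area=(15.0, 15.0), generations=100, num_samples=30,
        sequence_length=5e4, recomb_rate=1e-6, cutoff=75.0,
    )
    rng = np.random.default_rng(seed)
    arg_s2, mid_s2, comp_run, realized = [], [], [], []
    ks = None
    for _ in range(replicates):
        p = IBDParams(**{**base.__dict__, "seed": int(rng.integers(1, 2**31 - 1))})
        sim = simulate_ibd(p)
        arg = sim.arg
        nt = arg.num_trees()
        if ks is None:
            ks = sorted(set(np.unique(np.geomspace(1, nt, n_ks).astype(int))))
        ks = [min(k, nt) for k in ks]
        row_a, row_m = [], []
        for k in ks:
            sub = restrict_to_trees(arg, 0, k - 1)
            row_a.append(fit(sub).sigma2_scalar)
            row_m.append(midpoint_fit(sub).sigma2_scalar)
        comp = tree_composite_fit(arg, max_trees=max(ks))
        run = comp.running_average
        arg_s2.append(row_a)
        mid_s2.append(row_m)
        comp_run.append([float(run[min(k, len(run)) - 1]) for k in ks])
        realized.append(float(np.mean(sim.realized_dispersal)))
    from .simulate import effective_dispersal

    return BiasResult(ks, arg_s2, mid_s2, comp_run, realized,
                      effective_dispersal(base))
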