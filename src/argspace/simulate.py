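"""Test-data generators at two fidelity levels.

``simulate_model_arg`` + ``simulate_locations`` produce data exactly from the
inference model: a random ARG topology (coalescent with recombination, via
msprime's full-ARG recording) and node locations drawn from the joint
Gaussian with loop constraints imposed by exact conditioning (``meeting``
variant; loops behave as Brownian bridges) or from the forward midpoint model.

``simulate_ibd`` is a scaled-down individual-based 2D spatial simulation with
Gaussian mating and competition kernels, density-dependent reproduction,
reflecting habitat boundaries, discrete generations and full ARG recording —
the kind of process Brownian motion only approximates, used to probe the
model's biases.  Default parameters are desk-scale (hundreds of individuals,
hundreds of generations, a 100 kb chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
import tskit
from scipy.spatial import cKDTree

from .arg import SpatialARG, chop_arg, simplify_arg
from .likelihood import ModelSpec
from .oracle import build_joint

__all__ = [
    "IBDParams",
    "SimOutput",
    "simulate_model_arg",
    "simulate_locations",
    "with_sample_locations",
    "simulate_ibd",
    "realized_dispersal",
    "effective_dispersal",
]


# --------------------------------------------------------------------- model


def simulate_model_arg(
    ns: int,
    target_recombinations: float = 0.0,
    root_count: int | None = None,
    seed: int = 1,
    ndim: int = 1,
    population_size: float = 1e4,
    sequence_length: float = 1e5,
) -> SpatialARG:
    """Random valid ARG topology with ``ns`` samples.

    The recombination rate is set so the expected number of recombination
    nodes matches ``target_recombinations`` (events occur at rate ρL on the
    total branch length, whose coalescent expectation is 2N·H(ns−1)).  Sample
    locations are initialized to zero placeholders — draw real ones with
    :func:`simulate_locations`.  If ``root_count`` > 1 the ARG is chopped at
    the time that best achieves that many roots.
    """
    if ns < 1:
        raise ValueError("ns must be >= 1")
    harmonic = sum(1.0 / k for k in range(1, max(ns, 2))) if ns > 1 else 1.0
    expected_total = 2.0 * population_size * harmonic
    rate = target_recombinations / (expected_total * sequence_length)
    ts = msprime.sim_ancestry(
        samples=ns,
        ploidy=1,
        population_size=population_size,
        sequence_length=sequence_length,
        recombination_rate=rate,
        record_full_arg=True,
        random_seed=max(int(seed), 1),
    )
    cols = ["x", "y"][:ndim]
    loc = pd.DataFrame(0.0, index=list(ts.samples()), columns=cols)
    loc.index.name = "node_id"
    arg = SpatialARG.from_tskit(ts, loc)
    if root_count is not None and root_count > len(arg.roots):
        arg = _chop_to_root_count(arg, root_count)
    return arg


def _chop_to_root_count(arg: SpatialARG, root_count: int) -> SpatialARG:
    times = sorted(set(arg.nodes["time"]))
    candidates = [0.5 * (a + b) for a, b in zip(times[:-1], times[1:])]
    best, best_diff = None, None
    for c in reversed(candidates):  # prefer the deepest qualifying cutoff
        nroots = len(chop_arg(arg, c).roots)
        diff = abs(nroots - root_count)
        if best_diff is None or diff < best_diff:
            best, best_diff = c, diff
        if nroots >= root_count:
            break
    return chop_arg(arg, best) if best is not None else arg


def simulate_locations(
    arg: SpatialARG,
    model: ModelSpec,
    variant: str = "meeting",
    seed: int = 1,
    max_vars: int = 100_000,
) -> pd.DataFrame:
    """Draw locations for every node of a chopped ARG.

    ``meeting``: the full node-location vector is drawn from the joint
    Gaussian conditioned on both parental lineages meeting at each
    recombination node (loops behave as Brownian bridges).  ``midpoint``: a
    forward pass placing each recombination node at the unweighted average of
    its two parents' Brownian endpoints.  Roots sit at the model's μ.
    """
    rng = np.random.default_rng(seed)
    roots = arg.roots
    mu = np.atleast_2d(np.asarray(model.mu, float))
    if mu.shape == (1, 1) or mu.shape[0] == 1 and len(roots) != 1:
        mu = np.broadcast_to(mu, (len(roots), mu.shape[-1])).copy()
    d = model.ndim
    cols = ["x", "y"][:d]
    if variant == "meeting":
        jg = build_joint(arg, mu, model.sigma2, max_vars=max_vars)
        jg = jg.condition_on_loops()
        draws = jg.sample(rng)
        return pd.DataFrame.from_dict(
            {int(k): np.atleast_1d(v) for k, v in draws.items()},
            orient="index",
            columns=cols,
        ).sort_index()
    if variant != "midpoint":
        raise ValueError("variant must be 'meeting' or 'midpoint'")
    Sigma = np.atleast_2d(np.asarray(model.sigma2, float))
    L = np.linalg.cholesky(Sigma)
    ridx = {r: i for i, r in enumerate(roots)}
    locs: dict[int, np.ndarray] = {}
    for v in arg.nodes_by_time(reverse=True):
        parents = arg.parents_of(v)
        if not parents:
            locs[v] = mu[ridx[v]].astype(float)
            continue
        ends = []
        for p in parents:
            t = arg.edge_length(v, p)
            disp = L @ rng.standard_normal(d) * np.sqrt(t)
            ends.append(locs[p] + disp)
        locs[v] = np.mean(ends, axis=0)
    return pd.DataFrame.from_dict(locs, orient="index", columns=cols).sort_index()


def with_sample_locations(arg: SpatialARG, node_locations: pd.DataFrame) -> SpatialARG:
    """Return a copy of ``arg`` whose sample locations are taken from a full
    node-location table (as produced by :func:`simulate_locations`)."""
    loc = node_locations.loc[arg.sample_ids].copy()
    loc.index.name = "node_id"
    return SpatialARG(arg.nodes, arg.edges, loc, arg.sequence_length, validate=False)


# ----------------------------------------------------------------------- IBD


@dataclass
class IBDParams:
    """Parameters of the individual-based 2D spatial simulation.

    Kernel variances are in squared spatial units; the effective dispersal
    rate of the recorded genealogy is σd² + σm²/2 (offspring displacement
    plus half the mother–father distance variance).  Interaction radii are
    truncated at three standard deviations of each kernel.
    """

    n0: int = 400
    area: tuple[float, float] = (25.0, 25.0)
    sigma_d2: float = 0.25
    sigma_m2: float = 0.25
    sigma_c2: float = 0.25
    generations: int = 300
    sequence_length: float = 1e5
    recomb_rate: float = 1e-6
    num_samples: int = 50
    cutoff: float | None = None
    seed: int = 1


@dataclass
class SimOutput:
    """Recorded ARG, true per-node locations and realized dispersal."""

    arg: SpatialARG
    true_node_locations: pd.DataFrame
    realized_dispersal: np.ndarray
    params: IBDParams
    population_sizes: list[int] = field(default_factory=list)


def effective_dispersal(params: IBDParams) -> float:
    """σd² + σm²/2: per-dimension dispersal rate implied by the kernels,
    ignoring boundary reflections."""
    return params.sigma_d2 + 0.5 * params.sigma_m2


def _reflect(x: np.ndarray, width: float) -> np.ndarray:
    """Reflect coordinates into [0, width] (repeatedly, via the triangular
    wave of period 2·width)."""
    y = np.mod(x, 2.0 * width)
    return np.where(y > width, 2.0 * width - y, y)


def _gamete_edges(rng, child_node, genome_a, genome_b, L, rate, edges):
    nbreaks = rng.poisson(rate * L)
    breaks = np.sort(rng.uniform(0.0, L, size=nbreaks)) if nbreaks else np.array([])
    bounds = np.concatenate([[0.0], breaks, [L]])
    cur = genome_a if rng.random() < 0.5 else genome_b
    other = genome_b if cur == genome_a else genome_a
    for i in range(len(bounds) - 1):
        l, r = bounds[i], bounds[i + 1]
        if r > l:
            edges.append((cur, child_node, l, r))
        cur, other = other, cur


def simulate_ibd(params: IBDParams) -> SimOutput:
    """Discrete-generation spatial Wright–Fisher-style simulation.

    Each individual acts once as a mother, choosing a mate by a Gaussian
    kernel (variance σm²) among neighbours within 3σm of itself; with no mate
    in range it leaves no offspring.  Offspring numbers are Poisson with mean
    2/(1+C), where C sums area-normalised Gaussian interaction strengths
    (variance σc²) over neighbours within 3σc.  Offspring are displaced from
    the mother by N(0, σd²) per dimension, reflected off the habitat
    boundary.  The full inheritance graph is recorded, then restricted to the
    sampled genomes, pass-through chains are pruned, and (optionally) the ARG
    is chopped at ``params.cutoff``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    W, H = p.area
    sig_m = np.sqrt(p.sigma_m2)
    sig_c = np.sqrt(p.sigma_c2)
    r_m, r_c = 3.0 * sig_m, 3.0 * sig_c
    norm_c = 1.0 / (2.0 * np.pi * p.sigma_c2)

    pos = np.column_stack(
        [rng.uniform(0, W, p.n0), rng.uniform(0, H, p.n0)]
    )
    node_times: list[int] = []   # forward generation of each genome node
    node_locs: list[tuple] = []
    genomes = np.arange(2 * p.n0).reshape(p.n0, 2)
    for i in range(p.n0):
        node_times.extend([0, 0])
        node_locs.extend([tuple(pos[i])] * 2)
    edges: list[tuple] = []
    pop_sizes = [p.n0]

    for gen in range(1, p.generations + 1):
        n = len(pos)
        if n == 0:
            raise RuntimeError(f"population went extinct at generation {gen - 1}")
        tree = cKDTree(pos)
        mate_lists = tree.query_ball_point(pos, r_m)
        comp_lists = tree.query_ball_point(pos, r_c)
        new_pos, new_genomes = [], []
        for i in range(n):
            mates = [j for j in mate_lists[i] if j != i]
            if not mates:
                continue
            dm = np.linalg.norm(pos[mates] - pos[i], axis=1)
            wts = np.exp(-0.5 * dm**2 / p.sigma_m2)
            tot = wts.sum()
            if tot <= 0:
                continue
            father = mates[rng.choice(len(mates), p=wts / tot)]
            comp = [j for j in comp_lists[i] if j != i]
            dc = np.linalg.norm(pos[comp] - pos[i], axis=1) if comp else np.array([])
            C = float(np.sum(norm_c * np.exp(-0.5 * dc**2 / p.sigma_c2)))
            lam = 2.0 / (1.0 + C)
            for _ in range(rng.poisson(lam)):
                off = pos[i] + rng.normal(0.0, np.sqrt(p.sigma_d2), size=2)
                off = np.array([_reflect(off[0], W), _reflect(off[1], H)])
                child = len(node_times)
                node_times.extend([gen, gen])
                node_locs.extend([tuple(off)] * 2)
                _gamete_edges(
                    rng, child, int(genomes[i, 0]), int(genomes[i, 1]),
                    p.sequence_length, p.recomb_rate, edges,
                )
                _gamete_edges(
                    rng, child + 1, int(genomes[father, 0]), int(genomes[father, 1]),
                    p.sequence_length, p.recomb_rate, edges,
                )
                new_pos.append(off)
                new_genomes.append((child, child + 1))
        if not new_pos:
            raise RuntimeError(f"population went extinct at generation {gen}")
        pos = np.array(new_pos)
        genomes = np.array(new_genomes)
        pop_sizes.append(len(pos))

    # ------------------------------------------------------------ tables
    G = p.generations
    tables = tskit.TableCollection(sequence_length=p.sequence_length)
    times = G - np.asarray(node_times)
    n_final = len(pos)
    k = min(p.num_samples, n_final)
    sampled_inds = rng.choice(n_final, size=k, replace=False)
    sample_nodes = sorted(int(g) for i in sampled_inds for g in genomes[i])
    sample_set = set(sample_nodes)
    for v in range(len(times)):
        flags = tskit.NODE_IS_SAMPLE if v in sample_set else 0
        tables.nodes.add_row(flags=flags, time=float(times[v]))
    for (parent, child, l, r) in edges:
        tables.edges.add_row(left=l, right=r, parent=parent, child=child)
    tables.sort()
    ts = tables.tree_sequence()
    ts2, node_map = ts.simplify(
        samples=sample_nodes, keep_unary=True, map_nodes=True, filter_sites=True
    )
    old_of_new = np.full(ts2.num_nodes, -1, int)
    for old, new in enumerate(node_map):
        if new != tskit.NULL:
            old_of_new[new] = old
    loc_arr = np.array(node_locs)
    cols = ["x", "y"]
    sample_loc = pd.DataFrame(
        loc_arr[[old_of_new[int(v)] for v in ts2.samples()]],
        index=[int(v) for v in ts2.samples()],
        columns=cols,
    )
    sample_loc.index.name = "node_id"
    arg = SpatialARG.from_tskit(ts2, sample_loc)
    arg = simplify_arg(arg)
    truth = pd.DataFrame(
        loc_arr[[old_of_new[int(v)] for v in arg.nodes.index]],
        index=[int(v) for v in arg.nodes.index],
        columns=cols,
    )
    truth.index.name = "node_id"
    if p.cutoff is not None:
        arg = chop_arg(arg, p.cutoff)
        truth = truth.loc[[v for v in arg.nodes.index if v in truth.index]]
    out = SimOutput(arg, truth, np.zeros(2), p, pop_sizes)
    out.realized_dispersal = realized_dispersal(out)
    return out


def realized_dispersal(sim: SimOutput) -> np.ndarray:
    """Average squared displacement per generation over ARG edges, per
    dimension (edges whose endpoints lack a true location — fresh chop roots
    — are skipped)."""
    arg = sim.arg
    truth = sim.true_node_locations
    acc = []
    for (c, pnode) in arg.edge_keys():
        if c not in truth.index or pnode not in truth.index:
            continue
        dt = arg.edge_length(c, pnode)
        dx = truth.loc[pnode].to_numpy(float) - truth.loc[c].to_numpy(float)
        acc.append(dx**2 / dt)
    if not acc:
        return np.full(2, np.nan)
    return np.mean(acc, axis=0)
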