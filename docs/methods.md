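# Methods

## Model

Each node of an ARG is a haploid genome; edges point from parent to child
and carry half-open genome intervals `[left, right)` in base pairs. Time is
in generations before the present. Forward in time, genetic material moves
by Brownian motion: the displacement along an edge of length t generations
is N(0, σ²t) per dimension (2D: dispersal matrix Σ with components σx², σy²,
σxy). Every edge counts equally regardless of genomic span: the graph is
taken as known, so short-span edges carry no extra uncertainty.

A recombination node — structurally, any node with two distinct parents —
creates a loop: its two parental lineages must occupy the same point in
space at the recombination time. Conditioning independent edgewise Brownian
motions on these meeting constraints is the entire content of the model; a
closed loop behaves as a Brownian bridge, so the recombination node of a
symmetric loop with top-to-node time t has variance σ²t/2 (half its
unconditioned value), and the shrinkage cascades to everything below.

Rather than conditioning explicitly, all quantities are computed from the
*unconditioned* path-tip distribution `Lp ~ N(Rμ, σ²Sp)`, where paths run
from samples to roots, `Sp` holds pairwise shared times (total length of
edges two paths traverse in common), and `P`, `R` are path–sample and
path–root incidence matrices. Evaluating at observations that place all
paths of a sample at the same point implicitly imposes the constraints; the
conditioned sample covariance is `S = (PᵀSp⁻P)⁻¹`. The dense conditioning
oracle (`argspace.oracle`) verifies this equivalence exactly on every graph
the test suite generates, by explicit linear-Gaussian conditioning in
edge-displacement space.

### Roots

Chopping the ARG at a cutoff time truncates every crossing edge with a
fresh root node at exactly the cutoff (one per crossing child–parent pair,
ids above all existing ids, assigned in ascending child order). Roots are
modelled as independent with zero variance by default; `add_root_variance`
relaxes this by adding a shared (or per-root) variance to same-root path
pairs. A chop can pass *through* a loop, leaving a recombination node whose
parents reach two distinct roots. Such open loops are treated as
constraint-free by `find_loops` but are still implicitly conditioned on by
the likelihood (two paths to one sample must coincide); `fit` reports their
count in `diagnostics["n_open_loops"]`. Two consequences, established
numerically in the test suite:

* with only closed loops, the expected dispersal MLE is exactly
  σ²(ns − nr)/ns — the classic GLS degrees-of-freedom factor; with open
  loops the surviving cross-root constraint changes the expectation, so the
  `ns/(ns − nr)` correction should only be trusted on closed-loop graphs;
* the root-location/dispersal MLEs are the argmax of the conditioned
  sample-space likelihood for closed-loop graphs (verified against a
  numerical optimizer); for open loops the printed estimator is retained
  as the method's definition.

### Estimators

`μ̂ = (RᵀSp⁻R)⁻¹RᵀSp⁻Pℓ*` (generalized least squares; the pseudoinverse and
a warning are used when roots are non-identifiable, e.g. two fresh roots
capping the two parents of one recombination node) and
`σ̂² = residᵀSp⁻resid/ns`. The ns denominator is the sample-space MLE; a
REML-style `ns − nr` denominator is available (`denominator="reml"`, off by
default). In 2D the residual cross-products give Σ̂ directly, and the
likelihood uses the Kronecker factorization Σ ⊗ Sp rather than a 2np
matrix.

Ancestor locations condition one (arbitrary) node-to-root path on the
minimal sample paths. The result is invariant to the path choice (asserted
by testing both sides of a loop); the implementation always walks to the
smaller-id parent for determinism. The variance factor V splits into a
Brownian-motion part (t_a − s_aᵀSp⁻s_a) and a root-uncertainty part; σ̂² and
μ̂ enter as plug-ins — dispersal-estimation uncertainty is *not* propagated
into V. Mid-edge ancestors extend the child node's path by the partial
edge; shared time accrues linearly along the edge, matching Brownian
motion.

## Minimal path set

The full path set grows like 2^k along lineages with k recombination nodes.
A linearly sufficient subset of size ns + (#recombination nodes) is built in
one tip-to-root traversal: nodes are processed in increasing (time, id)
order; every lineage at a node continues to its smaller-id parent; at a
recombination node exactly one duplicate is routed to the larger-id parent.
Sufficiency (the induced sample matrix equals the full-basis one) is an
invariant of the test suite, checked to 1e-10 on random graphs. Whether
this particular subset matches any other implementation's choice is
irrelevant: S is basis-invariant. Shared times are then accumulated per
edge over the paths containing it.

## Numerical choices

* Pseudoinverse truncation: eigenvalues below `1e-10 × dimension × max|λ|`
  are treated as zero (configurable `rtol`).
* Singular `Sp`: the likelihood uses the pseudo-determinant on the support;
  observations with an off-support residual component (relative tolerance
  1e-6) return −inf with the interpretation that a coincidence constraint
  is violated. The minimal basis, the default everywhere, avoids the
  perfectly-correlated duplicate tips that make the full basis degenerate.
* Negative Brownian variance components beyond −1e-8 raise (they signal an
  `s_a` inconsistent with the path basis); small negatives clip to zero.
* The oracle is dense O(n³) and capped at 200 node copies by default; it is
  a correctness reference, not a production path. Its variables are one
  location per node plus one "right copy" per recombination node;
  constraints are left copy = right copy, conditioned in one shot in
  displacement space with pseudoinverses for redundant constraint sets.

## Model variant and baselines

* Midpoint variant: the parents of a recombination node may be any distance
  apart; the node sits at their unweighted average (½–½, no span
  weighting). Implemented by propagating averaging weights over edge
  displacements top-down; sample covariance, fits and node variances come
  from the weight vectors. For a single loop the recombination node's
  variance is again σ²t/2, but on-loop parents (and lineages branching off
  the loop) keep their unconditioned variance.
* Per-tree composite: the single-tree model fitted to each marginal tree,
  averaged (no importance sampling).
* Averaging-up: each node at the plain mean of its children's locations,
  branch lengths ignored, on the ARG simplified of pass-through chains;
  single-child nodes copy their child. Estimates are invariant to node
  times by construction.

## Simulators

`simulate_model_arg` delegates the coalescent-with-recombination event
sequence to msprime (full-ARG recording) with the recombination rate chosen
so the expected number of recombination nodes hits a target
(ρL·2N·H(ns−1) = target); `simulate_locations` then draws *all* node
locations either exactly from the loop-conditioned Gaussian (`meeting`,
via the oracle) or by a forward midpoint pass, so estimators can be checked
against interior truth. Draws are reproducible given a seed.

`simulate_ibd` is a discrete-generation, individual-based 2D simulation:
hermaphrodites, each acting once as mother; mate choice by a Gaussian
kernel (variance σm², truncated at 3σm, no selfing; no mate in range → no
offspring); offspring counts Poisson with mean 2/(1+C), where C sums
area-normalized Gaussian interaction strengths (variance σc², radius 3σc)
over neighbours — normalization makes the equilibrium density ≈1 per unit²
regardless of σc; offspring displaced from the mother by N(0, σd²) per
dimension with repeated boundary reflection. The full inheritance graph is
recorded (tskit tables), restricted to the sampled genomes keeping unary
ancestors, then pass-through chains are pruned so that only sample,
coalescent, recombination and root nodes remain; parallel same-parent edges
merge (as in simplified tree sequences). The effective dispersal rate is
σd² + σm²/2; the realized rate (mean squared displacement per generation
over ARG edges, per dimension) is measured from the recorded true
locations and is slightly lower under reflecting boundaries.

Default scale — 400 founders on a 25×25 area (carrying capacity ≈625),
σd² = σm² = σc² = 0.25, 100 kb at 10⁻⁶ recombination per bp per
generation, 300 generations, 50 sampled diploids — is chosen so a full
simulate-fit-validate cycle runs in seconds on one CPU while still yielding
hundreds of marginal trees; validation experiments in the test suite use
further reduced versions of the same process (≈150 founders, ≈100
generations). What these simulations emulate is local mate choice, local
density regulation and finite habitat; what they do not emulate is
overlapping generations, mortality structure, selection, or long-range
dispersal, so passing tests speak to model behaviour under smooth
isolation-by-distance, not to arbitrary real data.

## Experiments and what they show

* Coverage (`experiments.coverage_experiment`): on model-exact data with the
  true σ² (roots estimated), nominal 95% ancestor intervals cover the true
  locations at 95% within Monte-Carlo error — the conditional-Gaussian
  algebra and its degrees-of-freedom accounting are right.
* Bias (`experiments.bias_experiment`): on individual-based data the ARG
  estimate of σ² rises steadily with the number of trees included, the
  per-tree composite average stays flat (a boundary-driven underestimate),
  and the midpoint variant rises several-fold more slowly — the meeting
  constraint at recombination nodes, not Brownian motion per se, drives the
  overestimation.

## Known limitations

* The ARG is assumed known; no inference from sequence data, no mutation
  handling, no importance sampling over tree posteriors.
* Gaussian dispersal only; habitat boundaries are simulated but not
  corrected for in the likelihood.
* No joint distribution across multiple ancestors is exposed (the oracle
  computes pairwise covariances, but the public API returns marginals).
* Dispersal estimates on real-scale ARGs inherit the documented
  recombination-loop bias; windowed fits (`windowed_fit`) trade bias
  against variance but there is no principled window-size rule.
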