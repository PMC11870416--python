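"""Conditional ancestor-location distributions and confidence regions."""

import numpy as np
import pytest

import argspace as a
from argspace.ancestors import ancestor_mean, ancestor_variance
from argspace.paths import ancestor_shared_times

from conftest import make_located_arg


def fast_path_ancestor(arg, node, ps, Sp, mu_hat):
    y = arg.locations_array
    sa, ta, ridx = ancestor_shared_times(arg, node, ps)
    mean = ancestor_mean(sa, ta, ridx, Sp, ps.P, ps.R, y, mu_hat)
    V, bm, root = ancestor_variance(sa, ta, ridx, Sp, ps.R)
    return np.asarray(mean).ravel(), V, bm, root


class TestTrivialCases:
    def test_sample_node_conditions_on_itself(self, fig1_arg):
        ps = a.minimal_paths(fig1_arg)
        Sp = a.shared_times(fig1_arg, ps).Sp
        mu = a.mle_root_locations(Sp, ps.P, ps.R, fig1_arg.locations_array)
        for s in fig1_arg.sample_ids:
            mean, V, _, _ = fast_path_ancestor(fig1_arg, s, ps, Sp, mu)
            assert mean[0] == pytest.approx(
                float(fig1_arg.locations.loc[s, "x"]), abs=1e-9
            )
            assert V == pytest.approx(0.0, abs=1e-9)

    def test_root_node_gets_mu_hat_and_root_uncertainty(self, fig1_arg):
        ps = a.minimal_paths(fig1_arg)
        Sp = a.shared_times(fig1_arg, ps).Sp
        mu = a.mle_root_locations(Sp, ps.P, ps.R, fig1_arg.locations_array)
        mean, V, bm, root = fast_path_ancestor(fig1_arg, 6, ps, Sp, mu)
        assert mean[0] == pytest.approx(float(mu[0, 0]))
        assert bm == pytest.approx(0.0, abs=1e-10)
        # closed form for a single root: (1ᵀ Sp⁻ 1)⁻¹
        from argspace.likelihood import generalized_inverse

        ones = np.ones(ps.np_)
        expected = 1.0 / float(ones @ generalized_inverse(Sp) @ ones)
        assert root == pytest.approx(expected, rel=1e-10)


class TestOracleParity:
    @pytest.mark.parametrize("seed", range(1, 7))
    def test_mean_and_variance_match_dense_conditioning(self, seed):
        arg, _, _ = make_located_arg(seed=seed, ns=6, target_recombinations=2.0)
        ps = a.minimal_paths(arg)
        Sp = a.shared_times(arg, ps).Sp
        mu_hat = a.mle_root_locations(Sp, ps.P, ps.R, arg.locations_array)
        jg = a.oracle.build_joint(
            arg, np.zeros((len(arg.roots), 1)), 1.0, max_vars=500
        ).condition_on_loops()
        for v in arg.nodes.index:
            v = int(v)
            mean, V, _, _ = fast_path_ancestor(arg, v, ps, Sp, mu_hat)
            mo, Vo = jg.conditional_ancestor(v, root_prior="flat")
            np.testing.assert_allclose(mean, mo, atol=1e-8)
            assert V == pytest.approx(Vo, abs=1e-8)

    def test_path_choice_invariance(self, fig1_arg):
        """sa from either side of the loop yields the same conditional."""
        ps = a.minimal_paths(fig1_arg)
        Sp = a.shared_times(fig1_arg, ps).Sp
        y = fig1_arg.locations_array
        mu = a.mle_root_locations(Sp, ps.P, ps.R, y)
        # node E (3): canonical path goes via F (4); alternative goes via G
        alt_edges = [(3, 5), (5, 6)]
        sa_alt = np.zeros(ps.np_)
        for i, p in enumerate(ps.paths):
            es = {(p[k], p[k + 1]) for k in range(len(p) - 1)}
            sa_alt[i] = sum(
                fig1_arg.edge_length(c, q) for (c, q) in set(alt_edges) & es
            )
        ta = fig1_arg.node_time(6) - fig1_arg.node_time(3)
        sa, ta0, ridx = ancestor_shared_times(fig1_arg, 3, ps)
        assert ta0 == ta
        m1 = ancestor_mean(sa, ta, ridx, Sp, ps.P, ps.R, y, mu)
        m2 = ancestor_mean(sa_alt, ta, ridx, Sp, ps.P, ps.R, y, mu)
        np.testing.assert_allclose(m1, m2, atol=1e-8)
        V1, _, _ = ancestor_variance(sa, ta, ridx, Sp, ps.R)
        V2, _, _ = ancestor_variance(sa_alt, ta, ridx, Sp, ps.R)
        assert V1 == pytest.approx(V2, abs=1e-8)


class TestVarianceDominance:
    def test_arg_no_less_certain_than_tree(self, fig1_arg):
        """With the same σ², the ARG's variance factor never exceeds the
        single marginal tree's for nodes on a shared path."""
        ps = a.minimal_paths(fig1_arg)
        Sp = a.shared_times(fig1_arg, ps).Sp
        tree = fig1_arg.restrict(0.0, 0.5)  # tree containing E-F-G chain
        tps = a.minimal_paths(tree)
        tSp = a.shared_times(tree, tps).Sp
        mu_arg = a.mle_root_locations(Sp, ps.P, ps.R, fig1_arg.locations_array)
        mu_tree = a.mle_root_locations(tSp, tps.P, tps.R, tree.locations_array)
        for node in [3, 4, 5]:
            _, V_arg, _, _ = fast_path_ancestor(fig1_arg, node, ps, Sp, mu_arg)
            _, V_tree, _, _ = fast_path_ancestor(tree, node, tps, tSp, mu_tree)
            assert V_arg <= V_tree + 1e-9

    @pytest.mark.parametrize("seed", [2, 4])
    def test_variance_never_exceeds_unconditional(self, seed):
        arg, _, _ = make_located_arg(seed=seed, ns=6, target_recombinations=2.0)
        ps = a.minimal_paths(arg)
        Sp = a.shared_times(arg, ps).Sp
        for v in arg.nodes.index:
            v = int(v)
            sa, ta, ridx = ancestor_shared_times(arg, v, ps)
            _, bm, _ = ancestor_variance(sa, ta, ridx, Sp, ps.R)
            # the Brownian component is bounded by the unconditional ta
            assert bm <= ta + 1e-9


@pytest.fixture(scope="module")
def fitted():
    arg, locs, model = make_located_arg(seed=9, ns=6, target_recombinations=2.0)
    return arg, locs, a.fit(arg)


class TestLocateAncestor:

    def test_time_zero_returns_sample(self, fitted):
        arg, _, res = fitted
        s = arg.sample_ids[0]
        out = a.locate_ancestor(arg, s, 10.0, 0.0, res)
        assert out.mean[0] == pytest.approx(float(arg.locations.loc[s, "x"]))
        assert out.V == pytest.approx(0.0, abs=1e-9)

    def test_node_time_matches_node_distribution(self, fitted):
        arg, _, res = fitted
        s = arg.sample_ids[0]
        # first coalescent node on this sample's lineage at position 0
        from argspace.ancestors import _edge_at

        v = arg.parents_of(s)[0]
        t = arg.node_time(v)
        node, parent = _edge_at(arg, s, 0.0, t)
        out = a.locate_ancestor(arg, s, 0.0, t, res)
        ps, Sp = res.path_set, res.Sp
        mu = res.mu_hat
        mean, V, _, _ = fast_path_ancestor(res.arg, node, ps, Sp, mu)
        np.testing.assert_allclose(out.mean, mean, atol=1e-10)
        assert out.V == pytest.approx(V, abs=1e-10)

    def test_mid_edge_interpolates_between_nodes(self, fitted):
        arg, _, res = fitted
        s = arg.sample_ids[0]
        v = arg.parents_of(s)[0]
        t = arg.node_time(v)
        below = a.locate_ancestor(arg, s, 0.0, 0.5 * t, res)
        at_child = a.locate_ancestor(arg, s, 0.0, 0.0, res)
        at_parent = a.locate_ancestor(arg, s, 0.0, t, res)
        assert at_child.V - 1e-12 <= below.V
        assert below.bm_component <= at_parent.bm_component + 0.5 * t

    def test_time_above_root_errors(self, fitted):
        arg, _, res = fitted
        with pytest.raises(a.ARGError):
            a.locate_ancestor(arg, arg.sample_ids[0], 10.0,
                              2 * float(arg.nodes["time"].max()), res)

    def test_position_outside_sequence_errors(self, fitted):
        arg, _, res = fitted
        with pytest.raises(a.ARGError):
            a.locate_ancestor(arg, arg.sample_ids[0],
                              arg.sequence_length + 1.0, 0.0, res)


class TestConfidenceRegion:
    def test_degenerate_point(self):
        loc = a.AncestorLocation(node=1, time=0.0, mean=np.array([2.0]),
                                 V=0.0, bm_component=0.0, root_component=0.0,
                                 sigma2=np.array([[1.0]]))
        lo, hi = a.confidence_region(loc, 0.95)
        assert lo == hi == 2.0

    def test_gaussian_quantile_95(self):
        loc = a.AncestorLocation(node=1, time=0.0, mean=np.array([1.0]),
                                 V=4.0, bm_component=4.0, root_component=0.0,
                                 sigma2=np.array([[1.0]]))
        lo, hi = a.confidence_region(loc, 0.95)
        assert hi - 1.0 == pytest.approx(1.959964 * 2.0, abs=1e-4)

    def test_2d_ellipse(self):
        loc = a.AncestorLocation(node=1, time=0.0, mean=np.array([0.0, 0.0]),
                                 V=1.0, bm_component=1.0, root_component=0.0,
                                 sigma2=np.diag([4.0, 1.0]))
        ell = a.confidence_region(loc, 0.95)
        assert ell["semi_axes"][1] == pytest.approx(
            2 * ell["semi_axes"][0], rel=1e-9
        )

    def test_invalid_level(self):
        loc = a.AncestorLocation(node=1, time=0.0, mean=np.array([0.0]),
                                 V=1.0, bm_component=1.0, root_component=0.0,
                                 sigma2=np.array([[1.0]]))
        with pytest.raises(ValueError):
            a.confidence_region(loc, 1.5)
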