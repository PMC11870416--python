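"""Root-location and dispersal MLEs, fit drivers, windowing, and the
recovery properties of the estimators on model-consistent data."""

import numpy as np
import pytest
from scipy import optimize, stats

import argspace as a
from argspace.likelihood import generalized_inverse

from conftest import build_arg, make_located_arg


class TestRootLocationMLE:
    def test_constant_data_gives_constant_root(self):
        arg, _, _ = make_located_arg(seed=3, ns=6, target_recombinations=2.0)
        loc = arg.locations.copy()
        loc["x"] = 3.7
        arg = a.SpatialARG(arg.nodes, arg.edges, loc, arg.sequence_length)
        ps = a.minimal_paths(arg)
        Sp = a.shared_times(arg, ps).Sp
        mu = a.mle_root_locations(Sp, ps.P, ps.R, arg.locations_array)
        np.testing.assert_allclose(mu, 3.7)

    def test_symmetric_star_gives_zero(self, two_sample_tree):
        ps = a.minimal_paths(two_sample_tree)
        Sp = a.shared_times(two_sample_tree, ps).Sp
        mu = a.mle_root_locations(Sp, ps.P, ps.R, two_sample_tree.locations_array)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "seed,target,chop", [(1, 2.0, None), (5, 2.0, None), (5, 0.0, 0.3)]
    )
    def test_mle_is_argmax_of_conditioned_likelihood(self, seed, target, chop):
        """μ̂ and σ̂² jointly maximize the conditioned sample-location
        likelihood N(Bμ, σ²S) (numerical-optimizer oracle; the mean map B and
        sample matrix S come from the dense conditioning oracle)."""
        from scipy.stats import multivariate_normal

        arg, _, _ = make_located_arg(seed=seed, ns=5,
                                     target_recombinations=target,
                                     chop_frac=chop)
        ps = a.minimal_paths(arg)
        Sp = a.shared_times(arg, ps).Sp
        y = arg.locations_array
        mu_hat = a.mle_root_locations(Sp, ps.P, ps.R, y)
        s2_hat = float(a.mle_dispersal(Sp, ps.P, ps.R, y, mu_hat)[0, 0])
        nr = len(arg.roots)
        jg = a.oracle.build_joint(
            arg, np.zeros((nr, 1)), 1.0, max_vars=500
        ).condition_on_loops()
        S = jg.sample_cov()
        B = jg.M_eff[[jg.var_index(s) for s in arg.sample_ids]]

        def nll(theta):
            m = (B @ np.asarray(theta[:-1])[:, None]).ravel()
            return -multivariate_normal(
                mean=m, cov=np.exp(theta[-1]) * S, allow_singular=True
            ).logpdf(y.ravel())

        x0 = np.concatenate([mu_hat.ravel() + 0.4, [np.log(s2_hat) + 0.3]])
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 40_000},
        )
        np.testing.assert_allclose(res.x[:-1], mu_hat.ravel(), atol=1e-4)
        assert np.exp(res.x[-1]) == pytest.approx(s2_hat, rel=1e-4)

    def test_root_mle_maximizes_path_likelihood(self, fig1_arg):
        """For any fixed σ², μ̂ from the GLS formula beats perturbed root
        locations under the path likelihood."""
        ps = a.minimal_paths(fig1_arg)
        Sp = a.shared_times(fig1_arg, ps).Sp
        y = fig1_arg.locations_array
        mu_hat = a.mle_root_locations(Sp, ps.P, ps.R, y)
        best = a.log_likelihood(Sp, ps.P, ps.R, y, mu_hat, 0.5)
        for delta in [-0.3, 0.11, 2.0]:
            assert best >= a.log_likelihood(
                Sp, ps.P, ps.R, y, mu_hat + delta, 0.5
            )


class TestDispersalMLE:
    def test_zero_residual_zero_dispersal(self, two_sample_tree):
        loc = two_sample_tree.locations.copy()
        loc["x"] = 1.5
        arg = a.SpatialARG(two_sample_tree.nodes, two_sample_tree.edges, loc)
        ps = a.minimal_paths(arg)
        Sp = a.shared_times(arg, ps).Sp
        mu = a.mle_root_locations(Sp, ps.P, ps.R, arg.locations_array)
        s2 = a.mle_dispersal(Sp, ps.P, ps.R, arg.locations_array, mu)
        assert s2[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_closed_form(self):
        arg = build_arg(
            nodes=[(0, 0, 1), (1, 9.0, 0)],
            edges=[(1, 0, 0, 1)],
            locations={"node_id": [0], "x": [3.0]},
        )
        ps = a.minimal_paths(arg)
        Sp = a.shared_times(arg, ps).Sp
        s2 = a.mle_dispersal(Sp, ps.P, ps.R, arg.locations_array, np.zeros((1, 1)))
        assert s2[0, 0] == pytest.approx(3.0**2 / 9.0)

    def test_reml_denominator(self, two_sample_tree):
        ps = a.minimal_paths(two_sample_tree)
        Sp = a.shared_times(two_sample_tree, ps).Sp
        y = two_sample_tree.locations_array
        mu = a.mle_root_locations(Sp, ps.P, ps.R, y)
        mle = a.mle_dispersal(Sp, ps.P, ps.R, y, mu)
        reml = a.mle_dispersal(Sp, ps.P, ps.R, y, mu, denominator="reml")
        assert reml[0, 0] == pytest.approx(mle[0, 0] * 2 / (2 - 1))

    def test_mean_recovery_matches_ns_minus_nr_factor(self):
        """On model-consistent (closed-loop) data the MLE is biased by
        exactly (ns − nr)/ns; the analytic trace of the residual quadratic
        form confirms the constant for each topology."""
        ratios = []
        for seed in [2, 3, 4]:
            arg, _, model = make_located_arg(seed=seed, ns=8,
                                             target_recombinations=3.0)
            ps = a.minimal_paths(arg)
            Sp = a.shared_times(arg, ps).Sp
            Spg = generalized_inverse(Sp)
            S = a.sample_matrix(Sp, ps.P)
            A = ps.R.T @ Spg @ ps.R
            H = ps.R @ np.linalg.pinv(A) @ ps.R.T @ Spg
            M = np.eye(len(Sp)) - H
            analytic = np.trace(M.T @ Spg @ M @ ps.P @ S @ ps.P.T)
            assert analytic == pytest.approx(arg.ns - len(arg.roots), abs=1e-8)
            for rep in range(40):
                locs = a.simulate_locations(arg, model, "meeting",
                                            seed=100 * seed + rep)
                y = locs.loc[arg.sample_ids].to_numpy()
                mu = a.mle_root_locations(Sp, ps.P, ps.R, y)
                s2 = float(a.mle_dispersal(Sp, ps.P, ps.R, y, mu)[0, 0])
                ratios.append(s2 * arg.ns / (arg.ns - len(arg.roots)))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestFitDriver:
    def test_tree_collapse(self):
        """A zero-recombination ARG fits identically to the single-tree
        baseline."""
        arg, _, _ = make_located_arg(seed=6, ns=6, target_recombinations=0.0)
        whole = a.fit(arg)
        comp = a.tree_composite_fit(arg)
        assert len(comp.tree_fits) == 1
        tree = comp.tree_fits[0]
        np.testing.assert_allclose(whole.mu_hat, tree.mu_hat)
        np.testing.assert_allclose(whole.sigma2_hat, tree.sigma2_hat)
        assert whole.loglik == pytest.approx(tree.loglik)

    @pytest.mark.parametrize("seed", [7, 12])
    def test_path_loglik_at_profiled_mle_beats_truth(self, seed):
        """The path likelihood profiled at μ̂ (σ² = quad/rank) is at least
        its value at the generating parameters."""
        arg, _, model = make_located_arg(seed=seed, ns=6,
                                         target_recombinations=2.0)
        res = a.fit(arg)
        ps, Sp = res.path_set, res.Sp
        y = arg.locations_array
        rank = np.linalg.matrix_rank(Sp)
        quad = float(res.sigma2_hat) * res.ns  # Eq. 6 is quad / ns
        profile = a.log_likelihood(Sp, ps.P, ps.R, y, res.mu_hat, quad / rank)
        ll_truth = a.log_likelihood(
            Sp, ps.P, ps.R, y, model.mu, float(model.sigma2)
        )
        assert profile >= ll_truth - 1e-9

    def test_equivariance_under_translation(self):
        arg, _, _ = make_located_arg(seed=8, ns=6, target_recombinations=2.0)
        res = a.fit(arg)
        loc = arg.locations.copy()
        loc["x"] += 11.0
        arg2 = a.SpatialARG(arg.nodes, arg.edges, loc, arg.sequence_length)
        res2 = a.fit(arg2)
        np.testing.assert_allclose(res2.mu_hat, res.mu_hat + 11.0, atol=1e-8)
        np.testing.assert_allclose(res2.sigma2_hat, res.sigma2_hat, atol=1e-10)

    def test_diagnostics_report_recombination_and_open_loops(self, fig1_arg):
        res = a.fit(fig1_arg)
        assert res.diagnostics["n_recombination_nodes"] == 1
        assert res.diagnostics["n_open_loops"] == 0
        chopped = a.fit(fig1_arg, cutoff=1.5)
        assert chopped.diagnostics["n_open_loops"] == 1


@pytest.fixture(scope="module")
def ibd_arg():
    p = a.IBDParams(n0=100, area=(12.0, 12.0), generations=60,
                    num_samples=12, sequence_length=3e4,
                    recomb_rate=1e-6, seed=11)
    return a.simulate_ibd(p).arg


class TestWindowedFit:

    def test_zero_half_width_is_single_tree(self, ibd_arg):
        wf = a.windowed_fit(ibd_arg, 0, 0)
        comp = a.tree_composite_fit(ibd_arg, max_trees=1)
        np.testing.assert_allclose(wf.sigma2_hat, comp.tree_fits[0].sigma2_hat)

    def test_huge_half_width_is_whole_fit(self, ibd_arg):
        wf = a.windowed_fit(ibd_arg, 1, ibd_arg.num_trees() + 5)
        whole = a.fit(ibd_arg)
        np.testing.assert_allclose(wf.sigma2_hat, whole.sigma2_hat)

    def test_focal_out_of_range(self, ibd_arg):
        with pytest.raises(ValueError):
            a.windowed_fit(ibd_arg, ibd_arg.num_trees() + 3, 1)


class TestBiasTrend:
    def test_model_consistent_data_shows_no_systematic_trend(self):
        """When each k-tree sub-ARG is fitted to data simulated from its own
        loop-conditioned model, the corrected dispersal estimate shows no
        drift with k — the Fig.-5a-style increase is a model–process
        mismatch, not estimator inconsistency."""
        rhos = []
        for seed in [21, 22, 23]:
            arg, _, _ = make_located_arg(seed=seed, ns=10,
                                         target_recombinations=8.0)
            nt = arg.num_trees()
            ks = sorted(set(np.linspace(1, nt, 5, dtype=int)))
            vals = []
            for k in ks:
                sub = a.restrict_to_trees(arg, 0, k - 1)
                nr = len(sub.roots)
                model = a.ModelSpec(mu=np.zeros((nr, 1)), sigma2=1.0)
                corr = []
                for rep in range(12):
                    locs = a.simulate_locations(
                        sub, model, "meeting", seed=9000 * seed + 77 * k + rep
                    )
                    sub2 = a.with_sample_locations(sub, locs)
                    res = a.fit(sub2)
                    corr.append(
                        res.sigma2_scalar * res.ns / max(res.ns - res.nr, 1)
                    )
                vals.append(float(np.mean(corr)))
            rhos.append(stats.spearmanr(ks, vals).statistic)
        # monotone bias would give mean rho ~ +1; here it should hover near 0
        assert abs(float(np.mean(rhos))) < 0.7
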