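import numpy as np
import pandas as pd
import pytest

from carocontrol.core_model import Phylogeny
from carocontrol.macroevolution import (
    _CtmcKernel,
    _build_Q,
    _offdiag_pairs,
    category_history,
    categories_to_control_class,
    ctmc_fit,
    ctmc_lnL,
    correlated_evolution_test,
    dietary_richness_class,
    evolution_rate_regression,
    independent_contrasts,
    trajectory_binning,
    z_class,
)
from carocontrol.trees import TreeArrays, rescale_to_mean_branch, yule_tree
from carocontrol.synthetic_data import simulate_ctmc_tips
from conftest import make_network


class TestCategoryHistory:
    def test_identical_networks_no_transitions(self, small_tree, chain):
        networks = {lab: chain for lab in small_tree.node_labels}
        h = category_history(networks, small_tree)
        assert h.n_category_changes == 0
        assert h.n_control_count_changes == 0
        assert set(h.categories.values()) == {2}

    def test_planted_transition_recovered(self, small_tree, chain, merge_branch):
        networks = {lab: chain for lab in small_tree.node_labels}
        tip0 = small_tree.tip_labels[0]
        networks[tip0] = merge_branch  # category 2 -> 4 on one tip branch
        h = category_history(networks, small_tree)
        assert h.n_category_changes == 1
        event = h.transitions.iloc[0]
        assert (event["from"], event["to"]) == (2, 4) and event["child"] == tip0
        tally = h.event_table()
        assert tally["count"].sum() == h.n_category_changes

    def test_missing_network_errors(self, small_tree, chain):
        networks = {lab: chain for lab in small_tree.node_labels[:-1]}
        with pytest.raises(KeyError):
            category_history(networks, small_tree)


class TestCtmcFit:
    def test_rescaling_gives_exact_mean_branch(self, medium_tree):
        scaled, factor = rescale_to_mean_branch(medium_tree, 0.1)
        branches = scaled.blen[scaled.parent >= 0]
        assert branches.mean() == pytest.approx(0.1, rel=1e-12)

    def test_two_state_kernel_agrees_with_binary_pruning(self, small_tree):
        # shared-kernel consistency: the multi-state CTMC likelihood at k=2
        # must equal the binary pruning likelihood with a uniform root prior
        from carocontrol.ancestral import pruning_lnL

        states = {t: i % 2 for i, t in enumerate(small_tree.tip_labels)}
        q01, q10 = 0.04, 0.09
        Q = np.array([[-q01, q01], [q10, -q10]])
        a = ctmc_lnL(small_tree, states, Q, [0, 1])
        b = pruning_lnL(small_tree, states, q01, q10, root_prior="uniform")
        assert a == pytest.approx(b, abs=1e-10)

    def test_rate_rescaling_reciprocity(self, small_tree):
        # multiplying branch lengths by c divides fitted-scale rates by c:
        # the likelihood is invariant under (t, q) -> (c t, q / c)
        states = {t: i % 2 for i, t in enumerate(small_tree.tip_labels)}
        Q = _build_Q(np.array([0.3, 0.8]), 2, _offdiag_pairs(2))
        scaled, factor = rescale_to_mean_branch(small_tree, 0.1)
        a = ctmc_lnL(small_tree, states, Q, [0, 1])
        b = ctmc_lnL(scaled, states, Q / factor, [0, 1])
        assert a == pytest.approx(b, abs=1e-8)

    def test_fewer_than_two_states_errors(self, small_tree):
        with pytest.raises(ValueError):
            ctmc_fit(small_tree, {t: 3 for t in small_tree.tip_labels})

    def test_recovery_and_zero_rate_z(self):
        # 2-state chain with a planted zero loss rate (state 1 absorbing)
        tree = TreeArrays.from_phylogeny(yule_tree(48, 90.0, seed=8))
        scaled, _ = rescale_to_mean_branch(tree, 0.1)
        Q = np.array([[-2.0, 2.0], [0.0, 0.0]])
        tips = simulate_ctmc_tips(scaled, Q, seed=4, root_state=0)
        assert len(set(tips.values())) == 2
        model = ctmc_fit(
            tree, tips, mcmc_iterations=4000, mcmc_burnin=500, mcmc_thin=5, seed=0
        )
        z_gain = model.rates.loc[(0, 1), "z"]
        z_loss = model.rates.loc[(1, 0), "z"]
        assert z_loss > 0.5  # spike captures the planted zero
        assert z_gain < z_loss

    def test_z_class_bands(self):
        assert z_class(0.001) == "highly likely"
        assert z_class(0.05) == "likely"
        assert z_class(0.15) == "probable"
        assert z_class(0.5) == "unsupported"


class TestCharacterHelpers:
    def test_category_to_class_mapping(self):
        cats = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}
        classes = categories_to_control_class(cats)
        assert classes == {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}  # f excluded

    def test_dietary_richness_threshold(self, chain, merge_branch):
        nets = {"x": chain, "y": merge_branch}
        assert dietary_richness_class(nets, low_max=1) == {"x": 0, "y": 1}
        assert dietary_richness_class(nets, low_max=2) == {"x": 0, "y": 0}


class TestCorrelatedEvolution:
    def test_constant_character_rejected(self, small_tree):
        a = {t: 1 for t in small_tree.tip_labels}
        b = {t: i % 2 for i, t in enumerate(small_tree.tip_labels)}
        with pytest.raises(ValueError, match="constant"):
            correlated_evolution_test(small_tree, a, b, stones=2, iterations=10)

    def test_dependent_ml_at_least_independent(self, small_tree):
        # nesting: the 8-rate dependent model can represent any independent
        # model, so its ML likelihood cannot be lower
        from carocontrol.macroevolution import _ml_rates, _DEP_MAPPING, _INDEP_TIES

        rng = np.random.default_rng(0)
        tipsA = {t: int(rng.integers(2)) for t in small_tree.tip_labels}
        tipsB = {t: int(rng.integers(2)) for t in small_tree.tip_labels}
        tipsA[small_tree.tip_labels[0]] = 1 - tipsA[small_tree.tip_labels[1]]
        data = np.array(
            [2 * tipsA[t] + tipsB[t] for t in small_tree.tip_labels]
        )
        kernel = _CtmcKernel(small_tree, data, 4)
        _, lnl_dep = _ml_rates(kernel, _DEP_MAPPING, 4)

        def indep_mapping_lnl():
            import scipy.optimize as opt

            def build(rates):
                Q = np.zeros((4, 4))
                for r, pairs in _INDEP_TIES.items():
                    for i, j in pairs:
                        Q[i, j] = rates[r]
                np.fill_diagonal(Q, -Q.sum(axis=1))
                return Q

            lo, hi = np.log(1e-8), np.log(100.0)
            best = None
            for s in (1.0, 0.1):
                res = opt.minimize(
                    lambda x: -kernel.lnL(build(np.exp(x))),
                    np.full(4, np.log(s)), method="L-BFGS-B",
                    bounds=[(lo, hi)] * 4,
                )
                if best is None or res.fun < best.fun:
                    best = res
            return -best.fun

        assert lnl_dep >= indep_mapping_lnl() - 1e-6


class TestIndependentContrasts:
    def test_two_tip_closed_form(self):
        phylo = Phylogeny.from_newick("(A:2.0,B:3.0):0.0;", ultrametric=False)
        c = independent_contrasts(phylo, {"A": 5.0, "B": 1.0})
        assert c.contrasts.iloc[0] == pytest.approx((5.0 - 1.0) / np.sqrt(5.0))

    def test_constant_trait_zero_contrasts(self, medium_tree):
        c = independent_contrasts(medium_tree, {t: 3.3 for t in medium_tree.tip_labels})
        assert np.allclose(c.contrasts.to_numpy(), 0.0)

    def test_count_is_tips_minus_one(self, medium_tree):
        rng = np.random.default_rng(0)
        values = {t: float(rng.normal()) for t in medium_tree.tip_labels}
        c = independent_contrasts(medium_tree, values)
        assert len(c.contrasts) == medium_tree.n_tips - 1

    def test_polytomy_resolution_is_seeded(self):
        phylo = Phylogeny.from_newick("(A:1.0,B:1.0,C:1.0,D:1.0):0.0;")
        values = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 8.0}
        a = independent_contrasts(phylo, values, polytomy_seed=3)
        b = independent_contrasts(phylo, values, polytomy_seed=3)
        assert np.allclose(a.contrasts.to_numpy(), b.contrasts.to_numpy())

    def test_brownian_contrasts_standardized(self, medium_tree):
        # under Brownian motion, standardized contrasts are iid N(0, sigma^2):
        # mean ~ 0 and no inflation of variance with node depth
        rng = np.random.default_rng(5)
        x = np.zeros(medium_tree.n_nodes)
        for node in medium_tree.preorder():
            p = medium_tree.parent[node]
            if p >= 0:
                x[node] = x[p] + rng.normal(0, np.sqrt(medium_tree.blen[node]))
        values = {t: x[i] for i, t in enumerate(medium_tree.tip_labels)}
        c = independent_contrasts(medium_tree, values)
        z = c.contrasts.to_numpy()
        assert abs(z.mean()) < 3 * z.std(ddof=1) / np.sqrt(len(z))


class TestEvolutionRateRegression:
    def test_planted_internal_control_signal(self, small_tree, chain, merge_branch):
        # merge_branch has one more reaction-pair turnover and dNi=+1 against
        # chain; alternate networks so dNi aligns with turnover exactly
        networks = {}
        for i, lab in enumerate(small_tree.node_labels):
            networks[lab] = chain if i % 2 == 0 else merge_branch
        fit = evolution_rate_regression(networks, small_tree)
        assert fit.n_branches > 0
        assert abs(fit.coefficients["dNi"]) >= abs(fit.coefficients["dNs"]) - 1e-9

    def test_identical_networks_error(self, small_tree, chain):
        networks = {lab: chain for lab in small_tree.node_labels}
        with pytest.raises(ValueError, match="undefined"):
            evolution_rate_regression(networks, small_tree)


class TestTrajectoryBinning:
    def _ancestral_set(self, tree, network):
        from carocontrol.ancestral import AncestralNetworkSet

        networks = {lab: network for lab in tree.internal_labels}
        return AncestralNetworkSet(networks, {}, pd.DataFrame(index=tree.internal_labels))

    def test_identical_profiles_zero_amplitude(self, medium_tree, merge_branch):
        anc = self._ancestral_set(medium_tree, merge_branch)
        traj = trajectory_binning(anc, medium_tree, bin_width=10, max_age=45)
        assert traj.cycle_amplitude["all"] == pytest.approx(0.0, abs=1e-12)
        assert set(traj.bins["eta_i"].round(12)) == {round(1 / 3, 12)}

    def test_binning_convention_left_open_right_closed(self, merge_branch):
        # a node at age exactly 10 my goes to bin (0, 10]; age 12 -> (10, 20]
        phylo = Phylogeny.from_newick(
            "((A:10.0,B:10.0):2.0,(C:11.0,D:11.0):1.0):0.0;"
        )
        tree = TreeArrays.from_phylogeny(phylo)
        anc = self._ancestral_set(tree, merge_branch)
        traj = trajectory_binning(anc, tree, bin_width=10, max_age=45)
        bins = traj.bins.reset_index()
        # node at age exactly 10 -> bin (0, 10]; ages 11 and 12 -> (10, 20]
        assert dict(zip(bins["bin_start_my"], bins["n_nodes"])) == {0.0: 1, 10.0: 2}

    def test_rebinning_aggregates_consistently(self, medium_tree, merge_branch):
        anc = self._ancestral_set(medium_tree, merge_branch)
        fine = trajectory_binning(anc, medium_tree, bin_width=5, max_age=45)
        coarse = trajectory_binning(anc, medium_tree, bin_width=15, max_age=45)
        assert fine.bins["n_nodes"].sum() == coarse.bins["n_nodes"].sum()

    def test_empty_clade_errors(self, medium_tree, merge_branch):
        anc = self._ancestral_set(medium_tree, merge_branch)
        with pytest.raises(ValueError):
            trajectory_binning(anc, medium_tree, clades={"none": []})
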