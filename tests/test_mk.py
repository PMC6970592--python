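import numpy as np
import pytest
from scipy.linalg import expm

from dimorphasr import (BINARY_STATES, TERNARY_STATES, MkModel, fit_rates,
                        log_likelihood, log_likelihood_brute_force,
                        marginal_asr, marginal_posteriors_brute_force,
                        parse_newick, simulate_tree, transition_matrix)

from conftest import random_tips, random_tree


def er2(q, prior="uniform"):
    return MkModel(states=BINARY_STATES, rates=(q,), root_prior=prior)


def er3(q):
    return MkModel(states=TERNARY_STATES, rates=(q,))


class TestTransitionMatrix:
    def test_t_zero_is_identity(self):
        for model in (er2(0.7), er3(1.3)):
            assert np.allclose(transition_matrix(model, 0.0),
                               np.eye(model.k), atol=1e-14)

    def test_long_branch_tends_to_uniform(self):
        for model in (er2(0.5), er3(0.5)):
            P = transition_matrix(model, 1e4)
            assert np.allclose(P, 1.0 / model.k, atol=1e-12)

    def test_closed_form_value(self):
        # k=2, q=0.3, t=2: P_diff = (1 - e^{-1.2})/2
        P = transition_matrix(er2(0.3), 2.0)
        assert P[0, 1] == pytest.approx(0.5 * (1 - np.exp(-1.2)), abs=1e-12)
        assert P[0, 1] == pytest.approx(0.349403, abs=5e-7)

    @pytest.mark.parametrize("model", [er2(0.3), er3(0.8)],
                             ids=["k2", "k3"])
    def test_closed_form_agrees_with_matrix_exponential(self, model):
        for t in (0.01, 0.5, 2.0, 10.0):
            assert np.allclose(transition_matrix(model, t),
                               expm(model.Q() * t), atol=1e-10)

    def test_rows_stochastic_and_negative_t_rejected(self):
        model = MkModel(states=TERNARY_STATES, rate_structure="ARD",
                        rates=tuple(np.linspace(0.1, 0.6, 6)))
        P = transition_matrix(model, 1.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()
        with pytest.raises(ValueError):
            transition_matrix(model, -0.1)


class TestLikelihood:
    def test_cherry_same_state_no_change(self):
        tree = parse_newick("(A:1,B:1);")
        tips = {"A": "monomorphic", "B": "monomorphic"}
        # q -> 0: no change possible, likelihood = prior mass 1/2
        ll = log_likelihood(tree, tips, er2(1e-9))
        assert ll == pytest.approx(-np.log(2.0), abs=1e-6)

    def test_cherry_discordant_states_impossible_without_change(self):
        tree = parse_newick("(A:1,B:1);")
        tips = {"A": "monomorphic", "B": "dimorphic"}
        assert log_likelihood(tree, tips, er2(1e-12)) < -20.0

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_enumeration_oracle(self, k):
        states = BINARY_STATES if k == 2 else TERNARY_STATES
        rng = np.random.default_rng(k)
        for _ in range(20):
            tree = random_tree(rng, int(rng.integers(2, 7)))
            tips = random_tips(rng, tree, states)
            model = MkModel(states=states, rates=(float(rng.uniform(0.05, 2.0)),))
            assert log_likelihood(tree, tips, model) == pytest.approx(
                log_likelihood_brute_force(tree, tips, model), abs=1e-10)

    def test_missing_tip_state_is_fatal(self, rng):
        tree = random_tree(rng, 4)
        tips = {l: "monomorphic" for l in tree.leaf_labels()[:-1]}
        with pytest.raises(ValueError, match="without a tip state"):
            log_likelihood(tree, tips, er2(0.5))

    def test_unknown_state_label_is_fatal(self, rng):
        tree = random_tree(rng, 3)
        tips = {l: "weird" for l in tree.leaf_labels()}
        with pytest.raises(ValueError, match="weird"):
            log_likelihood(tree, tips, er2(0.5))


class TestMarginalASR:
    def test_symmetric_quartet_root_posterior_is_half(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": "monomorphic", "B": "dimorphic",
                "C": "monomorphic", "D": "dimorphic"}
        asr = marginal_asr(tree, tips, er2(0.4))
        assert asr.node_probs[tree.root.id] == pytest.approx([0.5, 0.5],
                                                             abs=1e-12)

    def test_low_rate_clade_concentrates_on_its_state(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": "dimorphic", "B": "dimorphic",
                "C": "dimorphic", "D": "dimorphic"}
        asr = marginal_asr(tree, tips, er2(1e-6))
        for probs in asr.node_probs.values():
            assert probs[1] > 0.999999

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_bruteforce_posteriors(self, k):
        states = BINARY_STATES if k == 2 else TERNARY_STATES
        rng = np.random.default_rng(10 + k)
        for _ in range(15):
            tree = random_tree(rng, int(rng.integers(2, 6)))
            tips = random_tips(rng, tree, states)
            model = MkModel(states=states, rates=(float(rng.uniform(0.05, 2.0)),))
            asr = marginal_asr(tree, tips, model)
            oracle = marginal_posteriors_brute_force(tree, tips, model)
            for nid, probs in oracle.items():
                assert asr.node_probs[nid] == pytest.approx(probs, abs=1e-10)
                assert asr.node_probs[nid].sum() == pytest.approx(1.0, abs=1e-9)

    def test_state_label_permutation_permutes_posteriors(self, rng):
        tree = random_tree(rng, 6)
        tips = random_tips(rng, tree, TERNARY_STATES)
        a = marginal_asr(tree, tips, er3(0.4))
        perm = (TERNARY_STATES[2], TERNARY_STATES[0], TERNARY_STATES[1])
        b = marginal_asr(tree, tips, MkModel(states=perm, rates=(0.4,)))
        for nid in a.node_probs:
            reordered = [b.node_probs[nid][perm.index(s)]
                         for s in TERNARY_STATES]
            assert a.node_probs[nid] == pytest.approx(reordered, abs=1e-12)

    def test_conditional_mode_runs_and_normalizes(self, rng):
        tree = random_tree(rng, 8)
        tips = random_tips(rng, tree, BINARY_STATES)
        asr = marginal_asr(tree, tips, er2(0.3), method="conditional")
        for probs in asr.node_probs.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestRerooting:
    def test_likelihood_invariant_under_rerooting(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            tree = random_tree(rng, int(rng.integers(4, 12)))
            tips = random_tips(rng, tree, BINARY_STATES)
            model = er2(float(rng.uniform(0.05, 1.5)), prior="stationary")
            ll = log_likelihood(tree, tips, model)
            internal = [n for n in tree.internal_nodes() if n is not tree.root]
            node = internal[rng.integers(len(internal))]
            ll2 = log_likelihood(tree.rerooted_at(node.id), tips, model)
            assert ll2 == pytest.approx(ll, abs=1e-9)


class TestFit:
    def test_all_identical_tips_hit_lower_bound(self, rng):
        tree = random_tree(rng, 8)
        tips = {l: "monomorphic" for l in tree.leaf_labels()}
        fit = fit_rates(tree, tips, BINARY_STATES)
        assert fit.at_lower_bound
        # likelihood decreases monotonically in q for uniform tips
        lls = [log_likelihood(tree, tips, er2(q)) for q in (1e-6, 0.1, 1.0)]
        assert lls[0] > lls[1] > lls[2]

    def test_local_optimality_of_fitted_rate(self, rng):
        tree = simulate_tree(60, 1.0, rng)
        model = er2(0.3)
        from dimorphasr import simulate_mk_history
        truth = simulate_mk_history(tree, model, rng)
        tips = {l.label: truth.true_node_states[l.id] for l in tree.leaves()}
        fit = fit_rates(tree, tips, BINARY_STATES)
        q_hat = fit.model.rates[0]
        assert fit.log_likelihood >= log_likelihood(tree, tips, er2(0.5 * q_hat))
        assert fit.log_likelihood >= log_likelihood(tree, tips, er2(2.0 * q_hat))

    def test_sym_ard_structures_fit(self, rng):
        tree = random_tree(rng, 10)
        tips = random_tips(rng, tree, TERNARY_STATES)
        for structure in ("SYM", "ARD"):
            fit = fit_rates(tree, tips, TERNARY_STATES,
                            rate_structure=structure)
            assert np.isfinite(fit.log_likelihood)
            assert fit.log_likelihood >= log_likelihood(
                tree, tips, er3(0.5)) - 1e-6
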