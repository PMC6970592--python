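import numpy as np
import pytest

from dimorphasr import (BINARY_STATES, MkModel, SimConfig, end_to_end_fixture,
                        simulate_mk_history, simulate_tree, simulate_volumes,
                        transition_matrix, yule_tip_count, effect_sizes,
                        normalize)
from dimorphasr.simulate import tree_depth


class TestYuleProcess:
    def test_expected_tip_count_matches_birth_process(self):
        """Over replicates, E[tips at time T] = exp(lambda*T) within 3 SE."""
        rng = np.random.default_rng(5)
        lam, T, n_rep = 1.0, 1.5, 1000
        counts = np.array([yule_tip_count(T, lam, rng) for _ in range(n_rep)])
        expected = np.exp(lam * T)
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(counts.mean() - expected) < 3 * se


class TestMkHistory:
    def test_tiny_rate_no_events(self, rng):
        tree = simulate_tree(10, 1.0, rng)
        model = MkModel(states=BINARY_STATES, rates=(1e-12,))
        truth = simulate_mk_history(tree, model, rng)
        assert truth.true_events == []
        states = set(truth.true_node_states.values())
        assert len(states) == 1

    def test_events_explain_state_differences(self, rng):
        tree = simulate_tree(15, 1.0, rng)
        model = MkModel(states=BINARY_STATES, rates=(0.3,))
        truth = simulate_mk_history(tree, model, rng)
        # an edge changes state iff it carries an odd-length event chain
        per_edge: dict[int, list] = {}
        for child_id, a, b in truth.true_events:
            per_edge.setdefault(child_id, []).append((a, b))
        for node in tree.preorder():
            if node is tree.root:
                continue
            differs = (truth.true_node_states[node.id]
                       != truth.true_node_states[node.parent.id])
            chain = per_edge.get(node.id, [])
            if differs:
                assert chain and chain[0][0] == \
                    truth.true_node_states[node.parent.id]
                assert chain[-1][1] == truth.true_node_states[node.id]
            elif chain:
                assert chain[0][0] == chain[-1][1]

    def test_endpoint_distribution_matches_transition_matrix(self):
        """Tip state frequencies on one long branch match P(t) rows."""
        model = MkModel(states=BINARY_STATES, rates=(0.4,))
        t, n_rep = 1.7, 2000
        rng = np.random.default_rng(3)
        from dimorphasr import parse_newick
        tree = parse_newick(f"(A:{t},B:1e-12);")
        hits = 0
        for _ in range(n_rep):
            truth = simulate_mk_history(tree, model, rng,
                                        root_state="monomorphic")
            hits += truth.true_node_states[tree.find_leaf("A").id] == "dimorphic"
        p = transition_matrix(model, t)[0, 1]
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(hits / n_rep - p) < 3 * se

    def test_expected_jump_count(self):
        """E[#jumps] = q*(k-1)*total branch length for ER, within 3 SE."""
        rng = np.random.default_rng(11)
        tree = simulate_tree(20, 1.0, rng)
        q, n_rep = 0.2, 400
        model = MkModel(states=BINARY_STATES, rates=(q,))
        counts = np.array([len(simulate_mk_history(tree, model, rng).true_events)
                           for _ in range(n_rep)])
        expected = q * (2 - 1) * tree.total_branch_length()
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(counts.mean() - expected) < 3 * se


class TestVolumes:
    def test_null_effect_sizes_mostly_monomorphic(self, rng):
        cfg = SimConfig(seed=1)
        states = {"hg1": {f"sp{i:02d}": "monomorphic" for i in range(1, 20)}}
        table = simulate_volumes(states, cfg, rng)
        eff = effect_sizes(normalize(table), muscles=("hg1",))
        calls = [e.state for e in eff]
        assert calls.count("monomorphic") >= 18  # type-I rate is tiny

    def test_body_scale_cancels_in_normalized_values(self):
        cfg_a = SimConfig(seed=2)
        cfg_b = SimConfig(seed=2, female_body_factor=2.3)
        states = {"hg1": {"spA": "male_enlarged"}}
        ta = simulate_volumes(states, cfg_a, np.random.default_rng(8))
        tb = simulate_volumes(states, cfg_b, np.random.default_rng(8))
        na = {(p.sex, p.specimen_id): p.norm_volumes for p in normalize(ta)}
        nb = {(p.sex, p.specimen_id): p.norm_volumes for p in normalize(tb)}
        for key, vols in na.items():
            for m, v in vols.items():
                assert nb[key][m] == pytest.approx(v, rel=1e-9)

    def test_realized_d_converges_to_target_at_large_n(self):
        """Mean realized d over seeded large-n replicates is within 2% of
        the generative target."""
        ds = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_per_sex=1000)
            table = simulate_volumes({"hg1": {"spA": "male_enlarged"}}, cfg,
                                     np.random.default_rng(3000 + seed))
            ds.append(effect_sizes(normalize(table), muscles=("hg1",),
                                   min_n=2)[0].d)
        assert np.mean(ds) == pytest.approx(2.5, rel=0.02)

    def test_realized_d_spread_at_study_n(self):
        """At n = 12/sex the sampling SD of d-hat is ~0.55, so most but not
        all replicates land within 0.6 of the target."""
        ds = []
        for rep in range(200):
            cfg = SimConfig(seed=0, n_per_sex=12)
            table = simulate_volumes({"hg1": {"spA": "male_enlarged"}}, cfg,
                                     np.random.default_rng(4000 + rep))
            ds.append(effect_sizes(normalize(table), muscles=("hg1",),
                                   min_n=2)[0].d)
        ds = np.asarray(ds)
        assert abs(np.median(ds) - 2.5) < 0.25
        assert np.mean(np.abs(ds - 2.5) <= 0.6) >= 0.6


class TestFixture:
    def test_default_config_record_arithmetic(self):
        bundle = end_to_end_fixture(SimConfig(seed=0))
        assert len(bundle.table.records) == 19 * 2 * 10
        assert len(bundle.tree.leaves()) == 19

    def test_hg4_truth_is_eventless(self):
        bundle = end_to_end_fixture(SimConfig(seed=0))
        assert bundle.truths["hg4"].true_events == []
        assert set(bundle.truths["hg4"].true_node_states.values()) == \
            {"monomorphic"}

    def test_determinism_byte_identical(self, tmp_path):
        from dimorphasr.io_data import write_volume_table, write_newick

        out = []
        for run in ("a", "b"):
            bundle = end_to_end_fixture(SimConfig(seed=9))
            pv, pt = tmp_path / f"v{run}.tsv", tmp_path / f"t{run}.nwk"
            write_volume_table(bundle.table, pv)
            write_newick(bundle.tree, pt)
            out.append(pv.read_bytes() + pt.read_bytes())
        assert out[0] == out[1]

    def test_state_recovery_in_low_rate_regime(self):
        """MAP reconstruction on true tip states recovers >= 80% of true
        internal states when q * depth <= 0.2."""
        from dimorphasr import marginal_asr

        rng = np.random.default_rng(21)
        accs = []
        for _ in range(20):
            tree = simulate_tree(19, 1.0, rng)
            q = 0.2 / (tree_depth(tree) + 1e-9) * 0.9
            model = MkModel(states=BINARY_STATES, rates=(q,))
            truth = simulate_mk_history(tree, model, rng)
            tips = {l.label: truth.true_node_states[l.id]
                    for l in tree.leaves()}
            asr = marginal_asr(tree, tips, model)
            internal = [n.id for n in tree.internal_nodes()]
            acc = np.mean([asr.map_states[n] == truth.true_node_states[n]
                           for n in internal])
            accs.append(acc)
        assert np.median(accs) >= 0.8
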