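"""Network model, exact inference, EM learning and serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import enumeration_posterior, random_ternary_net
from noisecare.bayes_net import (
    TABLE3_FIXTURE,
    BayesNetError,
    Cpt,
    DiscreteBayesNet,
    ImpossibleEvidenceError,
    NetworkVariable,
    build_study_network,
    build_table3_network,
    em_learn,
    infer_posterior,
    joint_probability,
    map_predict,
    read_network,
    write_network,
)


def _chain_truth_net() -> DiscreteBayesNet:
    """a -> b -> c with mixing rows bounded away from the simplex boundary."""
    variables = [NetworkVariable(n, ("a", "b", "c")) for n in ("v0", "v1", "v2")]
    net = DiscreteBayesNet(
        variables, parents={"v0": (), "v1": ("v0",), "v2": ("v1",)}
    )
    net.set_cpt(Cpt("v0", (), np.array([0.35, 0.35, 0.30])))
    rows = np.array([[0.6, 0.3, 0.1], [0.1, 0.6, 0.3], [0.3, 0.1, 0.6]])
    net.set_cpt(Cpt("v1", ("v0",), rows))
    net.set_cpt(Cpt("v2", ("v1",), rows[::-1]))
    return net


class TestModelValidation:
    def test_row_sum_violation_rejected(self):
        with pytest.raises(BayesNetError, match="sum to 1"):
            Cpt("x", (), np.array([0.5, 0.4]))

    def test_negative_probability_rejected(self):
        with pytest.raises(BayesNetError, match="negative"):
            Cpt("x", (), np.array([1.2, -0.2]))

    def test_cycle_rejected(self):
        variables = [
            NetworkVariable("a", ("0", "1")),
            NetworkVariable("b", ("0", "1")),
        ]
        with pytest.raises(BayesNetError, match="cycle"):
            DiscreteBayesNet(variables, parents={"a": ("b",), "b": ("a",)})

    def test_undeclared_parent_rejected(self):
        variables = [NetworkVariable("a", ("0", "1"))]
        with pytest.raises(BayesNetError, match="undeclared"):
            DiscreteBayesNet(variables, parents={"a": ("ghost",)})


class TestStudyStructure:
    def test_arc_set(self):
        net = build_study_network()
        arcs = set(net.arcs())
        assert len(arcs) == 15
        expected = {("exposure", "sensitivity")}
        expected |= {(p, "annoyance") for p in ("exposure", "sensitivity")}
        for aspect in ("psychosocial", "communicational", "physical"):
            expected |= {
                (p, aspect) for p in ("exposure", "sensitivity", "annoyance")
            }
            expected.add((aspect, "quality"))
        assert arcs == expected

    def test_acyclic_and_ternary(self):
        net = build_study_network()
        assert net.topological_order()[0] == "exposure"
        assert all(len(net.states(n)) == 3 for n in net.names)


class TestJointProbability:
    def test_single_variable_prior(self):
        net = DiscreteBayesNet(
            [NetworkVariable("x", ("s1", "s2"))], parents={"x": ()}
        )
        net.set_cpt(Cpt("x", (), np.array([0.2, 0.8])))
        assert joint_probability(net, {"x": "s1"}) == pytest.approx(0.2)

    def test_three_chain_hand_product(self):
        # P(a=1)=0.3; P(b=1|a=1)=0.9, P(b=1|a=0)=0.2; P(c=1|b=1)=0.6,
        # P(c=1|b=0)=0.1  =>  P(a=1,b=0,c=1) = 0.3 * 0.1 * 0.1 = 0.003
        variables = [NetworkVariable(n, ("0", "1")) for n in "abc"]
        net = DiscreteBayesNet(
            variables, parents={"a": (), "b": ("a",), "c": ("b",)}
        )
        net.set_cpt(Cpt("a", (), np.array([0.7, 0.3])))
        net.set_cpt(Cpt("b", ("a",), np.array([[0.8, 0.2], [0.1, 0.9]])))
        net.set_cpt(Cpt("c", ("b",), np.array([[0.9, 0.1], [0.4, 0.6]])))
        assert joint_probability(net, {"a": "1", "b": "0", "c": "1"}) == (
            pytest.approx(0.3 * 0.1 * 0.1)
        )

    def test_partial_assignment_rejected(self, two_node_net):
        with pytest.raises(BayesNetError, match="misses"):
            joint_probability(two_node_net, {"parent": "x"})


class TestInference:
    def test_no_evidence_returns_prior(self):
        net = DiscreteBayesNet(
            [NetworkVariable("x", ("s1", "s2", "s3"))], parents={"x": ()}
        )
        net.set_cpt(Cpt("x", (), np.array([0.5, 0.3, 0.2])))
        assert infer_posterior(net, "x", {}) == pytest.approx([0.5, 0.3, 0.2])

    def test_fixture_quality_rows(self):
        net = build_table3_network()
        cases = [
            ({"exposure": "low", "sensitivity": "moderate", "annoyance": "low"},
             (0.167, 0.083, 0.750)),
            ({"exposure": "high", "sensitivity": "high", "annoyance": "moderate"},
             (0.000, 0.000, 1.000)),
            ({"exposure": "moderate", "sensitivity": "high", "annoyance": "low"},
             (0.500, 0.500, 0.000)),
        ]
        for evidence, expected in cases:
            post = infer_posterior(net, "quality", evidence)
            assert post == pytest.approx(expected, abs=1e-9)

    def test_matches_enumeration_on_random_nets(self):
        # exhaustive cross-check of variable elimination against the
        # brute-force full-joint oracle on 200 seeded random DAGs
        rng = np.random.default_rng(20240)
        for trial in range(200):
            n_nodes = int(rng.integers(2, 9))
            net = random_ternary_net(rng, n_nodes)
            names = net.names
            n_ev = int(rng.integers(0, n_nodes))
            ev_nodes = list(rng.choice(names, size=n_ev, replace=False))
            evidence = {
                v: net.states(v)[int(rng.integers(0, 3))] for v in ev_nodes
            }
            query = str(rng.choice([n for n in names if n not in evidence]))
            try:
                got = infer_posterior(net, query, evidence)
            except ImpossibleEvidenceError:
                continue  # zero-probability evidence draw
            want = enumeration_posterior(net, query, evidence)
            np.testing.assert_allclose(got, want, atol=1e-9, rtol=0)

    def test_impossible_evidence_raises(self):
        variables = [NetworkVariable(n, ("0", "1")) for n in "ab"]
        net = DiscreteBayesNet(variables, parents={"a": (), "b": ("a",)})
        net.set_cpt(Cpt("a", (), np.array([1.0, 0.0])))
        net.set_cpt(Cpt("b", ("a",), np.array([[1.0, 0.0], [0.0, 1.0]])))
        with pytest.raises(ImpossibleEvidenceError):
            infer_posterior(net, "a", {"b": "1"})

    def test_posterior_is_probability_vector(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_ternary_net(rng, 5)
            post = infer_posterior(net, "v3", {"v0": "a"})
            assert np.all(post >= 0)
            assert post.sum() == pytest.approx(1.0, abs=1e-9)


class TestMapPredict:
    def test_argmax_state(self, two_node_net):
        # posterior of child given parent=x is (0.7, 0.3)
        assert map_predict(two_node_net, "child", {"parent": "x"}) == "a"

    def test_tie_breaks_by_state_order(self):
        net = DiscreteBayesNet(
            [NetworkVariable("x", ("s1", "s2", "s3"))], parents={"x": ()}
        )
        net.set_cpt(Cpt("x", (), np.array([0.5, 0.5, 0.0])))
        assert map_predict(net, "x", {}) == "s1"

    def test_deterministic_copy_always_correct(self):
        variables = [NetworkVariable(n, ("0", "1", "2")) for n in "ab"]
        net = DiscreteBayesNet(variables, parents={"a": (), "b": ("a",)})
        net.set_cpt(Cpt("a", (), np.full(3, 1 / 3)))
        net.set_cpt(Cpt("b", ("a",), np.eye(3)))
        for s in "012":
            assert map_predict(net, "b", {"a": s}) == s


class TestEMLearn:
    def test_complete_data_equals_relative_frequencies(self, two_node_net):
        data = pd.DataFrame(
            {
                "parent": ["x"] * 6 + ["y"] * 4,
                "child": ["a", "a", "a", "a", "b", "b", "a", "b", "b", "b"],
            }
        )
        net = em_learn(two_node_net.structure_copy(), data, seed=0)
        np.testing.assert_allclose(net.cpts["parent"].table, [0.6, 0.4])
        np.testing.assert_allclose(
            net.cpts["child"].table, [[4 / 6, 2 / 6], [1 / 4, 3 / 4]]
        )

    def test_unobserved_parent_configuration_uniform(self):
        variables = [NetworkVariable(n, ("low", "moderate", "high")) for n in "ab"]
        structure = DiscreteBayesNet(variables, parents={"a": (), "b": ("a",)})
        data = pd.DataFrame({"a": ["low"] * 8, "b": ["low", "high"] * 4})
        net = em_learn(structure, data, seed=0)
        np.testing.assert_allclose(
            net.cpts["b"].table[1], [1 / 3, 1 / 3, 1 / 3]
        )
        np.testing.assert_allclose(
            net.cpts["b"].table[2], [1 / 3, 1 / 3, 1 / 3]
        )

    def test_log_likelihood_non_decreasing_with_missing(self):
        rng = np.random.default_rng(11)
        truth = random_ternary_net(rng, 4, edge_prob=0.7)
        from noisecare.synthetic import TruthNetwork, sample_cohort

        data = sample_cohort(TruthNetwork(truth, 0), 300, seed=1)
        mask = rng.random(data.shape) < 0.25
        data = data.mask(mask)
        net = em_learn(truth.structure_copy(), data, seed=2, max_iter=40)
        lls = net.em_log_likelihoods_
        assert len(lls) >= 2
        assert all(b >= a - 1e-9 * (1 + abs(a)) for a, b in zip(lls, lls[1:]))

    def test_parameter_recovery_from_complete_cohort(self):
        # chain truth net with near-uniform mixing: every parent
        # configuration carries ~1700 expected counts at n = 5000, so the
        # 0.05 total-variation bound sits far above sampling noise
        from noisecare.synthetic import TruthNetwork, sample_cohort

        truth = _chain_truth_net()
        data = sample_cohort(TruthNetwork(truth, 0), 5000, seed=3)
        learned = em_learn(truth.structure_copy(), data, seed=4)
        for name in truth.names:
            cpt_t, cpt_l = truth.cpts[name], learned.cpts[name]
            for idx in np.ndindex(*cpt_t.table.shape[:-1]):
                sel = np.ones(len(data), dtype=bool)
                for p, i in zip(cpt_t.parents, idx):
                    sel &= (data[p] == truth.states(p)[i]).to_numpy()
                if sel.sum() < 50:
                    continue
                tv = 0.5 * np.abs(cpt_t.table[idx] - cpt_l.table[idx]).sum()
                assert tv <= 0.05

    def test_record_order_invariance(self, two_node_net):
        rng = np.random.default_rng(17)
        from noisecare.synthetic import TruthNetwork, sample_cohort

        data = sample_cohort(TruthNetwork(two_node_net, 0), 200, seed=5)
        shuffled = data.sample(frac=1.0, random_state=1)
        net1 = em_learn(two_node_net.structure_copy(), data, seed=6)
        net2 = em_learn(two_node_net.structure_copy(), shuffled, seed=6)
        for n in data.columns:
            np.testing.assert_allclose(
                net1.cpts[n].table, net2.cpts[n].table, atol=1e-12
            )

    def test_all_missing_variable_rejected(self, two_node_net):
        data = pd.DataFrame({"parent": [np.nan, np.nan], "child": ["a", "b"]})
        with pytest.raises(BayesNetError, match="non-missing"):
            em_learn(two_node_net.structure_copy(), data, seed=0)


class TestSerialization:
    def test_round_trip_study_network(self, tmp_path):
        rng = np.random.default_rng(19)
        net = random_ternary_net(rng, 5, edge_prob=0.6)
        path = tmp_path / "net.json"
        write_network(net, path)
        assert read_network(path) == net

    def test_fixture_row_values(self):
        net = read_network(TABLE3_FIXTURE)
        cpt = net.cpts["quality"]
        i = {s: k for k, s in enumerate(("low", "moderate", "high"))}
        np.testing.assert_allclose(
            cpt.table[i["moderate"], i["high"], i["low"]], [0.5, 0.5, 0.0]
        )
        np.testing.assert_allclose(
            cpt.table[i["high"], i["high"], i["moderate"]], [0.0, 0.0, 1.0]
        )

    def test_row_sum_violation_in_file_rejected(self, tmp_path):
        doc = {
            "variables": [{"name": "x", "states": ["a", "b"]}],
            "cpts": [
                {"child": "x", "parents": [], "rows": [{"given": [], "probs": [0.9, 0.2]}]}
            ],
        }
        import json

        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(BayesNetError, match="cpts\\[0\\]"):
            read_network(path)
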