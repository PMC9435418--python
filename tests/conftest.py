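"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from noisecare.bayes_net import Cpt, DiscreteBayesNet, NetworkVariable


def random_ternary_net(
    rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.5
) -> DiscreteBayesNet:
    """A random DAG over ternary variables with Dirichlet CPT rows."""
    names = [f"v{i}" for i in range(n_nodes)]
    variables = [NetworkVariable(n, ("a", "b", "c")) for n in names]
    parents: dict[str, tuple[str, ...]] = {}
    for i, name in enumerate(names):
        ps = [names[j] for j in range(i) if rng.random() < edge_prob]
        parents[name] = tuple(ps)
    net = DiscreteBayesNet(variables, parents=parents)
    for name in names:
        shape = tuple(3 for _ in parents[name]) + (3,)
        rows = rng.dirichlet(np.ones(3), size=shape[:-1] or (1,)).reshape(shape)
        net.set_cpt(Cpt(name, parents[name], rows))
    return net


def enumeration_posterior(
    net: DiscreteBayesNet, query: str, evidence: dict[str, str]
) -> np.ndarray:
    """Brute-force posterior from the explicitly assembled full joint.

    Builds the joint tensor by direct open-grid indexing of each CPT —
    deliberately a different code path from the variable-elimination
    machinery it checks.
    """
    names = net.names
    cards = [len(net.states(n)) for n in names]
    grids = np.meshgrid(*[np.arange(c) for c in cards], indexing="ij")
    joint = np.ones(tuple(cards))
    for name in names:
        cpt = net.cpts[name]
        idx = tuple(grids[names.index(p)] for p in cpt.parents) + (
            grids[names.index(name)],
        )
        joint = joint * cpt.table[idx]
    # condition on the evidence by zeroing non-matching slices
    for node, state in evidence.items():
        axis = names.index(node)
        k = net.state_index(node, state)
        sel = [slice(None)] * len(names)
        keep = np.zeros(cards[axis])
        keep[k] = 1.0
        shape = [1] * len(names)
        shape[axis] = cards[axis]
        joint = joint * keep.reshape(shape)
    axis = names.index(query)
    marg = joint.sum(axis=tuple(i for i in range(len(names)) if i != axis))
    return marg / marg.sum()


@pytest.fixture(scope="session")
def rng_factory():
    def make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)

    return make


@pytest.fixture(scope="session")
def two_node_net() -> DiscreteBayesNet:
    """parent -> child with P(child=a | parent=x) = 0.7 and known rows."""
    variables = [
        NetworkVariable("parent", ("x", "y")),
        NetworkVariable("child", ("a", "b")),
    ]
    net = DiscreteBayesNet(variables, parents={"parent": (), "child": ("parent",)})
    net.set_cpt(Cpt("parent", (), np.array([0.4, 0.6])))
    net.set_cpt(Cpt("child", ("parent",), np.array([[0.7, 0.3], [0.2, 0.8]])))
    return net
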