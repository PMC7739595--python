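"""Shared fixtures and generators for random test networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stressnet.bn.dag import Dag
from stressnet.bn.fit import CPT, DiscreteBayesNet
from stressnet.inference import sample_net


def random_discrete_net(
    seed: int,
    n_nodes: int = 5,
    amp: float = 0.45,
    p_arc: float = 0.25,
    max_parents: int = 2,
    n_states: int = 2,
) -> DiscreteBayesNet:
    """A random binary network with monotone, individually strong arcs.

    Child probabilities are additive in the parent states, so every
    parent shifts the child distribution by ``2*amp/n_parents`` — no
    parent is vacuous, and no XOR-style marginally invisible
    dependence can occur.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    dag = Dag(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_arc and len(dag.parents(nodes[order[j]])) < max_parents:
                dag.add_arc(nodes[order[i]], nodes[order[j]])
    state_names = tuple("s%d" % i for i in range(n_states))
    cpts: dict[str, CPT] = {}
    for n in nodes:
        ps = tuple(sorted(dag.parents(n)))
        k = len(ps)
        rows = []
        for cfg in range(2**k):
            bits = np.array([(cfg >> (k - 1 - i)) & 1 for i in range(k)], dtype=float)
            p = 0.5 + amp * float(np.sum(2 * bits - 1)) / k if k else 0.5
            rows.append([1 - p, p])
        cpts[n] = CPT(parents=ps, parent_cards=(2,) * k, states=state_names, table=np.array(rows))
    net = DiscreteBayesNet(dag=dag, states={n: state_names for n in nodes}, cpts=cpts)
    net.validate()
    return net


def random_soft_net(seed: int, n_nodes: int = 4) -> DiscreteBayesNet:
    """A random binary network with arbitrary (possibly weak) CPT rows."""
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    dag = Dag(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.5:
                dag.add_arc(nodes[order[i]], nodes[order[j]])
    cpts = {}
    for n in nodes:
        ps = tuple(sorted(dag.parents(n)))
        ncfg = 2 ** len(ps)
        p = rng.uniform(0.05, 0.95, size=ncfg)
        cpts[n] = CPT(
            parents=ps,
            parent_cards=(2,) * len(ps),
            states=("s0", "s1"),
            table=np.column_stack([1 - p, p]),
        )
    return DiscreteBayesNet(dag=dag, states={n: ("s0", "s1") for n in nodes}, cpts=cpts)


def sample_from(net: DiscreteBayesNet, n: int, seed: int) -> pd.DataFrame:
    return sample_net(net, n, seed=seed)


@pytest.fixture
def chain_net() -> DiscreteBayesNet:
    """A -> B -> C with strong links (hand-specified CPTs)."""
    dag = Dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
    mk = lambda ps, cards, tab: CPT(parents=ps, parent_cards=cards, states=("lo", "hi"), table=np.asarray(tab))
    cpts = {
        "A": mk((), (), [[0.5, 0.5]]),
        "B": mk(("A",), (2,), [[0.9, 0.1], [0.1, 0.9]]),
        "C": mk(("B",), (2,), [[0.8, 0.2], [0.3, 0.7]]),
    }
    return DiscreteBayesNet(dag=dag, states={n: ("lo", "hi") for n in "ABC"}, cpts=cpts)
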