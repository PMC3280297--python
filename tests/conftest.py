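"""Shared fixtures: hand-built toy networks and generated synthetic studies."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathscope import (
    Compound,
    ExpressionMatrix,
    MetabolicNetwork,
    Reaction,
    SyntheticSpec,
    generate_study,
)


def make_network(reactions: dict[str, tuple[set, set, set, bool]]) -> MetabolicNetwork:
    """Build a network from {rid: (genes, substrates, products, reversible)}."""
    compounds = {}
    rxns = {}
    for rid, (genes, subs, prods, rev) in reactions.items():
        for cid in set(subs) | set(prods):
            compounds.setdefault(
                cid, Compound(id=cid, name=cid.rsplit("_", 1)[0], compartment="c")
            )
        rxns[rid] = Reaction(
            id=rid,
            gene_ids=frozenset(genes),
            substrates=frozenset(subs),
            products=frozenset(prods),
            reversible=rev,
        )
    return MetabolicNetwork(compounds=compounds, reactions=rxns)


def expression_from_profiles(
    profiles: dict[str, list[float]],
    condition: str = "cond",
    n_replicates: int = 1,
    noise: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    cols = {}
    genes = sorted(profiles)
    arr = np.array([profiles[g] for g in genes], dtype=float)
    for t in range(arr.shape[1]):
        for rep in range(1, n_replicates + 1):
            eps = noise * rng.standard_normal(len(genes)) if noise else 0.0
            cols[(condition, float(t), rep)] = arr[:, t] + eps
    frame = pd.DataFrame(cols, index=genes)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["condition", "time", "replicate"]
    )
    return ExpressionMatrix(frame)


def weighted_graph(edges: dict[tuple[str, str], float]) -> nx.DiGraph:
    g = nx.DiGraph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=float(w))
    return g


def random_weighted_graph(
    n_nodes: int, p: float, seed: int, low: float = -1.0, high: float = 1.0
) -> nx.DiGraph:
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=seed, directed=True)
    g = nx.relabel_nodes(g, {i: f"R{i:02d}" for i in g.nodes})
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(low, high))
    return g


@pytest.fixture(scope="session")
def triangle_network() -> MetabolicNetwork:
    """A -> B -> C -> A, three reactions, one gene each."""
    return make_network(
        {
            "R1": ({"g1"}, {"A_c"}, {"B_c"}, False),
            "R2": ({"g2"}, {"B_c"}, {"C_c"}, False),
            "R3": ({"g3"}, {"C_c"}, {"A_c"}, False),
        }
    )


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def iid_graph() -> nx.DiGraph:
    """Random digraph with iid U(-1, 1) weights, the independence null."""
    return random_weighted_graph(60, 0.25, seed=3)
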