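"""GSEA-style enrichment of minimum-set path edges among all network edges.

Edges are ranked by correlation weight (descending); walking the ranked
list, the running sum rises by |w|^p / sum(|w|^p over members) on member
edges and falls by 1/(N - n) otherwise.  The enrichment score is the signed
maximum deviation from zero, and significance comes from re-drawing random
member sets of the same size.  A strongly positive score means the edges
selected by the minimum-set paths concentrate among the most positively
correlated edges of the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .scope_extraction import Scope

Edge = tuple[str, str]


def ranked_edges(g: nx.DiGraph) -> list[tuple[Edge, float]]:
    """Edges sorted by weight descending (ties by edge id, deterministic)."""
    return sorted(
        (((u, v), float(d["weight"])) for u, v, d in g.edges(data=True)),
        key=lambda item: (-item[1], item[0]),
    )


def minimum_set_edges(
    scopes: Mapping[str, Scope], combined: Iterable[str]
) -> set[Edge]:
    """Directed reaction-graph edges used by any combined-set witness path."""
    edges: set[Edge] = set()
    for sid in combined:
        for path in scopes[sid].members.values():
            edges.update(zip(path.reactions, path.reactions[1:]))
    return edges


def enrichment_score(
    member_edges: Iterable[Edge],
    all_edges: Sequence[tuple[Edge, float]],
    p: float = 1.0,
) -> float:
    """Classic weighted running-sum enrichment score (signed max deviation)."""
    members = set(member_edges)
    total = len(all_edges)
    n = len(members)
    if n == 0 or n == total:
        raise ValueError("member set must be a proper nonempty subset of all edges")
    if not members <= {e for e, _ in all_edges}:
        raise ValueError("member edges must be a subset of the ranked edges")
    weights = np.array(
        [abs(w) ** p if e in members else 0.0 for e, w in all_edges]
    )
    denom = weights.sum()
    if denom == 0:  # all member weights zero: fall back to unweighted steps
        weights = np.array([1.0 if e in members else 0.0 for e, _ in all_edges])
        denom = weights.sum()
    steps = np.where(weights > 0, weights / denom, -1.0 / (total - n))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class EnrichmentResult:
    """Observed score, the permuted-score reference, and its empirical p."""

    es: float
    perm_es: np.ndarray
    p: float

    @property
    def n_permutations(self) -> int:
        return int(self.perm_es.size)


def permutation_test(
    member_edges: Iterable[Edge],
    all_edges: Sequence[tuple[Edge, float]],
    n_permutations: int = 1000,
    seed: int = 0,
    p: float = 1.0,
) -> EnrichmentResult:
    """Empirical p of the observed score against random same-size edge sets."""
    members = set(member_edges)
    observed = enrichment_score(members, all_edges, p=p)
    rng = np.random.default_rng(seed)
    universe = [e for e, _ in all_edges]
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        draw = rng.choice(len(universe), size=len(members), replace=False)
        perm[i] = enrichment_score({universe[j] for j in draw}, all_edges, p=p)
    pval = float(np.mean(perm >= observed))
    return EnrichmentResult(es=observed, perm_es=perm, p=pval)
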