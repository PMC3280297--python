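"""Hub reactions of the minimum set and their expression clusters.

All witness paths of the combined minimum set are collapsed into one
undirected network of traversed reactions, each edge weighted by the number
of paths observed on it.  A maximum spanning tree of this traversal graph
exposes the most commonly traversed backbone; its highest-degree nodes are
the hub reactions.  Hub gene expression is z-scaled, k-means clustered
(k = 9 by default) and the cluster mean profiles are correlated with the
minimum-set metabolite profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import ExpressionMatrix, MetabolicNetwork, MetaboliteProfiles
from .scope_extraction import Scope


def collapse_paths(
    scopes: Mapping[str, Scope],
    selected: Iterable[str] | None = None,
) -> nx.Graph:
    """Traversal graph: witness-path edges weighted by traversal count.

    ``selected`` restricts to the scopes of the combined minimum set;
    direction is dropped, so u-v and v-u traversals accumulate together.
    """
    tg = nx.Graph()
    ids = sorted(selected) if selected is not None else sorted(scopes)
    for sid in ids:
        for path in scopes[sid].members.values():
            rxns = path.reactions
            tg.add_nodes_from(rxns)
            for u, v in zip(rxns, rxns[1:]):
                if tg.has_edge(u, v):
                    tg[u][v]["weight"] += 1
                else:
                    tg.add_edge(u, v, weight=1)
    return tg


def max_spanning_tree(tg: nx.Graph) -> nx.Graph:
    """Maximum-weight spanning forest (one tree per connected component).

    Kruskal with a documented deterministic tie-break: heavier edges first,
    equal weights resolved by sorted (u, v) endpoint order.
    """
    if tg.number_of_nodes() == 0:
        raise ValueError("traversal graph is empty")
    tree = nx.Graph()
    tree.add_nodes_from(tg.nodes)
    uf = nx.utils.UnionFind(tg.nodes)
    edges = sorted(
        ((min(u, v), max(u, v), d["weight"]) for u, v, d in tg.edges(data=True)),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    for u, v, w in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v, weight=w)
    return tree


def top_hubs(tree: nx.Graph, tg: nx.Graph | None = None, k: int = 10) -> list[str]:
    """The k most connected reactions of the spanning tree.

    Connectivity is tree degree; ties break by total incident traversal
    weight (on the full traversal graph when given, else the tree), then id.
    """
    import warnings

    weight_graph = tg if tg is not None else tree
    def keyfun(node: str):
        incident = weight_graph.degree(node, weight="weight") if node in weight_graph else 0
        return (-tree.degree(node), -incident, node)

    nodes = sorted(tree.nodes, key=keyfun)
    if len(nodes) < k:
        warnings.warn(
            f"only {len(nodes)} reactions in the traversal tree (asked for {k})"
        )
    return nodes[:k]


def zscale_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization; zero-variance rows map to all-zero profiles."""
    values = frame.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (values - mean) / sd, index=frame.index, columns=frame.columns
    )


@dataclass
class HubClusters:
    """K-means partition of hub gene profiles and the cluster means."""

    assignments: pd.Series  # gene -> cluster label
    means: pd.DataFrame  # cluster x time
    hub_genes: dict[str, list[str]]  # hub reaction -> genes

    @property
    def k(self) -> int:
        return self.means.shape[0]


def cluster_hub_expression(
    expr: ExpressionMatrix,
    net: MetabolicNetwork,
    hubs: Sequence[str],
    condition: str,
    k: int = 9,
    seed: int = 0,
    n_init: int = 20,
) -> HubClusters:
    """Cluster the z-scaled time profiles of all hub-reaction genes.

    k is reduced with a warning when there are fewer distinct profiles than
    clusters; a fixed seed makes the partition reproducible.
    """
    import warnings

    from sklearn.cluster import KMeans

    profiles = expr.condition_mean(condition)
    hub_genes = {
        h: sorted(net.reactions[h].gene_ids & set(profiles.index)) for h in hubs
    }
    genes = sorted({g for gs in hub_genes.values() for g in gs})
    if not genes:
        raise ValueError("no measured genes among the hub reactions")
    scaled = zscale_rows(profiles.loc[genes])
    n_distinct = np.unique(scaled.to_numpy().round(12), axis=0).shape[0]
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct hub gene profiles; reducing k from {k}"
        )
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(scaled.to_numpy())
    assignments = pd.Series(labels, index=genes, name="cluster")
    means = pd.DataFrame(
        km.cluster_centers_, columns=scaled.columns,
        index=pd.RangeIndex(k, name="cluster"),
    )
    return HubClusters(assignments=assignments, means=means, hub_genes=hub_genes)


def correlate_clusters_with_metabolites(
    clusters: HubClusters,
    profiles: MetaboliteProfiles,
    condition: str,
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each cluster mean with each metabolite profile.

    Returns a clusters x metabolites frame (heatmap-ready); metabolites with
    a constant profile are reported as missing.
    """
    metab = profiles.condition_mean(condition)
    if targets is not None:
        metab = metab.loc[[t for t in targets if t in metab.index]]
    times = list(clusters.means.columns)
    if list(metab.columns) != times:
        raise ValueError("metabolite and cluster time axes are not aligned")
    cm = clusters.means.to_numpy(dtype=float)
    mm = metab.to_numpy(dtype=float)
    n = cm.shape[1]

    def zrows(a: np.ndarray) -> np.ndarray:
        mean = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, (a - mean) / sd, np.nan)

    corr = zrows(cm) @ zrows(mm).T / n
    return pd.DataFrame(corr, index=clusters.means.index, columns=metab.index)


def minimum_set_bipartite(
    scopes: Mapping[str, Scope],
    combined: Iterable[str],
    hubs: Sequence[str],
) -> nx.Graph:
    """Bipartite graph linking minimum-set metabolites to the hub reactions
    their witness paths traverse."""
    bg = nx.Graph()
    hubset = set(hubs)
    for sid in sorted(combined):
        bg.add_node(sid, kind="metabolite", scope_size=scopes[sid].size)
        used = {r for p in scopes[sid].members.values() for r in p.reactions}
        for h in sorted(used & hubset):
            bg.add_node(h, kind="hub")
            bg.add_edge(sid, h)
    return bg
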