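"""End-to-end analysis: graph -> scopes -> minimum cover -> hubs.

Thin orchestration over the analysis modules, used by the CLI and by the
synthetic-study reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .enrichment_validation import (
    EnrichmentResult,
    minimum_set_edges,
    permutation_test,
    ranked_edges,
)
from .hub_analysis import (
    HubClusters,
    cluster_hub_expression,
    collapse_paths,
    correlate_clusters_with_metabolites,
    max_spanning_tree,
    top_hubs,
)
from .network_model import build_reaction_graph, weight_edges
from .path_significance import EdgeWeightECDF, fit_ecdf
from .scope_extraction import (
    Scope,
    SignificanceConfig,
    extract_all_scopes,
)
from .set_cover import (
    CoverProblem,
    CoverSolution,
    count_covered_reactions,
    enumerate_optima,
)
from .synthetic_data import CONDITION, StudyData


@dataclass
class PipelineResult:
    """Everything the full analysis produces for one condition."""

    graph: nx.DiGraph
    ecdf: EdgeWeightECDF
    scopes: dict[str, Scope]
    cover: CoverSolution
    traversal: nx.Graph
    tree: nx.Graph | None
    hubs: list[str]
    clusters: HubClusters | None
    cluster_metabolite_corr: pd.DataFrame | None
    enrichment: EnrichmentResult | None

    @property
    def max_scope_size(self) -> int:
        return max((s.size for s in self.scopes.values()), default=0)


def analyze_study(
    study: StudyData,
    lmax: int = 6,
    alpha_base: float = 0.05,
    k_hubs: int = 10,
    k_clusters: int = 9,
    n_enrichment_permutations: int = 1000,
    seed: int = 0,
    condition: str = CONDITION,
) -> PipelineResult:
    """Run the whole method on a generated (or loaded) study."""
    net = study.network
    g = weight_edges(
        build_reaction_graph(net), net, study.expression, condition
    )
    ecdf = fit_ecdf(g)
    cfg = SignificanceConfig.for_network(net, alpha_base)
    scopes = extract_all_scopes(g, net, ecdf, cfg, lmax=lmax)
    cover = enumerate_optima(CoverProblem.from_scopes(scopes))
    count_covered_reactions(cover, scopes)
    traversal = collapse_paths(scopes, cover.combined)
    tree = hubs = clusters = corr = enrichment = None
    if traversal.number_of_nodes():
        tree = max_spanning_tree(traversal)
        hubs = top_hubs(tree, traversal, k=k_hubs)
        clusters = cluster_hub_expression(
            study.expression, net, hubs, condition, k=k_clusters, seed=seed
        )
        corr = correlate_clusters_with_metabolites(
            clusters, study.metabolites, condition
        )
        edges = minimum_set_edges(scopes, cover.combined)
        ranked = ranked_edges(g)
        if 0 < len(edges) < len(ranked):
            enrichment = permutation_test(
                edges, ranked, n_permutations=n_enrichment_permutations, seed=seed
            )
    return PipelineResult(
        graph=g,
        ecdf=ecdf,
        scopes=scopes,
        cover=cover,
        traversal=traversal,
        tree=tree,
        hubs=hubs or [],
        clusters=clusters,
        cluster_metabolite_corr=corr,
        enrichment=enrichment,
    )
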