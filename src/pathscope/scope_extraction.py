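"""Metabolite scopes: compounds reachable by a significantly correlated path.

The scope of a compound c is the set of all compounds c' for which the most
significant path from the reactions consuming c to the reactions producing
c' clears a Bonferroni-corrected threshold.  Pseudo-nodes attach c to every
consuming reaction and c' to every producing reaction; among the per-length
best paths only the shortest significant one is kept as the witness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network_model import MetabolicNetwork
from .path_significance import (
    EdgeWeightECDF,
    Path,
    PathDP,
    ReferenceDistribution,
    best_paths_all_lengths,
)

logger = logging.getLogger(__name__)


def bonferroni_alpha(alpha_base: float, n_metabolites: int) -> float:
    """Per-test threshold alpha_base / n for n metabolites in the network."""
    if not 0.0 < alpha_base < 1.0:
        raise ValueError(f"alpha_base must be in (0, 1), got {alpha_base}")
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    return alpha_base / n_metabolites


@dataclass(frozen=True)
class SignificanceConfig:
    """Base significance level and the Bonferroni correction applied to it.

    ``n_tests`` defaults to the number of metabolites in the network, which
    is what the correction accounts for.
    """

    alpha_base: float = 0.05
    n_tests: int = 1

    def __post_init__(self) -> None:
        bonferroni_alpha(self.alpha_base, self.n_tests)  # validates

    @property
    def alpha_corrected(self) -> float:
        return bonferroni_alpha(self.alpha_base, self.n_tests)

    @classmethod
    def for_network(cls, net: MetabolicNetwork, alpha_base: float = 0.05):
        return cls(alpha_base=alpha_base, n_tests=len(net.compounds))


@dataclass
class Scope:
    """A source compound and the compounds its significant paths reach."""

    source: str
    members: dict[str, Path] = field(default_factory=dict)
    alpha_corrected: float = 0.05

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def witness(self, compound_id: str) -> Path:
        return self.members[compound_id]


def extract_scope(
    g: nx.DiGraph,
    net: MetabolicNetwork,
    compound_id: str,
    ecdf: EdgeWeightECDF,
    config: SignificanceConfig,
    ref: ReferenceDistribution | None = None,
    lmax: int = 30,
    candidates: list[str] | None = None,
) -> Scope:
    """Scope of one compound via a brute-force sweep over target compounds.

    A single forward dynamic program from the consuming reactions serves
    every candidate target; a candidate joins the scope when its minimum-p
    path is significant, with the shortest significant path as witness
    (ties: fewest edges, then smallest p, then lexicographic order — the
    per-length best is unique, so the first significant length decides).
    """
    if compound_id not in net.compounds:
        raise KeyError(f"compound {compound_id!r} not in network")
    alpha = config.alpha_corrected
    scope = Scope(source=compound_id, alpha_corrected=alpha)
    sources = [r for r in net.consumers(compound_id) if r in g]
    if not sources:
        logger.info("compound %s has no consuming reactions in the graph", compound_id)
        return scope
    dp = PathDP(g, ecdf, sources, lmax)
    if candidates is None:
        candidates = sorted(net.compounds)
    for cand in candidates:
        if cand == compound_id:
            continue
        targets = [r for r in net.producers(cand) if r in g]
        if not targets:
            continue
        paths = best_paths_all_lengths(
            g, ecdf, sources, targets, lmax,
            ref=ref, dp=dp, source=compound_id, target=cand,
        )
        significant = [p for p in paths if p.p <= alpha]
        if significant:
            # paths come ordered by length; the first is the shortest witness
            scope.members[cand] = significant[0]
    return scope


def extract_all_scopes(
    g: nx.DiGraph,
    net: MetabolicNetwork,
    ecdf: EdgeWeightECDF,
    config: SignificanceConfig,
    ref: ReferenceDistribution | None = None,
    lmax: int = 30,
    currency=None,
) -> dict[str, Scope]:
    """One scope per network compound (empty scopes included).

    Currency compounds are excluded both as sources and as candidate
    members: preprocessing removed their edges, so attaching pseudo-nodes
    through them would undo the currency correction.
    """
    from .network_model import DEFAULT_CURRENCY

    currency_ids = net.currency_compound_ids(
        DEFAULT_CURRENCY if currency is None else currency
    )
    compounds = sorted(set(net.compounds) - currency_ids)
    return {
        cid: extract_scope(
            g, net, cid, ecdf, config, ref=ref, lmax=lmax, candidates=compounds
        )
        for cid in compounds
    }


def scope_summary(scopes: dict[str, Scope]) -> pd.DataFrame:
    """Per-compound scope size table (the scope-size histogram input)."""
    return pd.DataFrame(
        {"compound": list(scopes), "scope_size": [s.size for s in scopes.values()]}
    ).set_index("compound")


def path_length_distribution(scopes: dict[str, Scope]) -> pd.Series:
    """Counts of witness-path lengths over all scopes."""
    lengths = [
        p.length for scope in scopes.values() for p in scope.members.values()
    ]
    return pd.Series(lengths, dtype=int).value_counts().sort_index()


def write_scopes(scopes: dict[str, Scope], out_dir) -> None:
    """One TSV per non-empty scope plus a summary TSV."""
    from pathlib import Path as FilePath

    out = FilePath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cid, scope in scopes.items():
        if not scope.members:
            continue
        rows = [
            {
                "member": member,
                "length": p.length,
                "score": p.score,
                "q": p.q,
                "p": p.p,
                "reactions": ";".join(p.reactions),
                "weights": ";".join(f"{w:.10g}" for w in p.weights),
            }
            for member, p in sorted(scope.members.items())
        ]
        pd.DataFrame(rows).to_csv(out / f"scope_{cid}.tsv", sep="\t", index=False)
    scope_summary(scopes).to_csv(out / "scope_summary.tsv", sep="\t")


def read_scopes(scope_dir) -> dict[str, Scope]:
    """Reload scopes written by :func:`write_scopes` (non-empty ones)."""
    from pathlib import Path as FilePath

    scopes: dict[str, Scope] = {}
    for path in sorted(FilePath(scope_dir).glob("scope_*.tsv")):
        if path.name == "scope_summary.tsv":
            continue
        cid = path.stem[len("scope_"):]
        frame = pd.read_csv(path, sep="\t")
        members = {}
        for row in frame.itertuples(index=False):
            weights = tuple(float(w) for w in str(row.weights).split(";"))
            members[row.member] = Path(
                reactions=tuple(str(row.reactions).split(";")),
                weights=weights,
                score=float(row.score),
                q=float(row.q),
                p_closed=float(row.p),
                source=cid,
                target=row.member,
            )
        scopes[cid] = Scope(source=cid, members=members)
    return scopes
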