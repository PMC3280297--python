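"""Metabolic network parsing and the correlation-weighted reaction graph.

The whole pipeline runs on a directed *reaction graph*: nodes are reactions,
and an edge u -> v exists whenever some non-currency compound is produced by
u and consumed by v.  Edge weights are the maximum Pearson correlation over
all pairwise gene combinations drawn from the two reactions' gene sets,
computed on replicate-averaged time-course expression for one condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Currency compounds removed before path analysis (ubiquitous cofactors and
#: carriers whose edges connect most of the network without pathway meaning).
DEFAULT_CURRENCY = frozenset(
    {
        "H+", "CoA", "H2O", "CO2", "Orthophosphate", "ATP", "ADP", "AMP",
        "FAD", "FADH2", "GDP", "GTP", "NAD", "NADH", "NADP", "NADPH", "UTP",
    }
)


class SBMLParseError(ValueError):
    """Raised when an SBML document cannot be converted into a network."""


@dataclass(frozen=True)
class Compound:
    """A metabolite species, compartment-qualified as in the SBML file."""

    id: str
    name: str
    compartment: str

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ValueError(f"compound {self.id!r} has an empty compartment")

    @property
    def base_name(self) -> str:
        """Compartment-free name used for currency matching."""
        return self.name or strip_compartment(self.id)


@dataclass(frozen=True)
class Reaction:
    """A reaction with its gene set and substrate/product compound ids."""

    id: str
    gene_ids: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def effective_substrates(self) -> frozenset[str]:
        """Compounds the reaction can consume (both sides if reversible)."""
        return self.substrates | self.products if self.reversible else self.substrates

    def effective_products(self) -> frozenset[str]:
        """Compounds the reaction can produce (both sides if reversible)."""
        return self.substrates | self.products if self.reversible else self.products


@dataclass
class MetabolicNetwork:
    """Compounds and reactions of a metabolic reconstruction."""

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            for cid in rxn.substrates | rxn.products:
                if cid not in self.compounds:
                    raise SBMLParseError(
                        f"reaction {rxn.id!r} references unknown species {cid!r}"
                    )

    def producers(self, compound_id: str) -> list[str]:
        """Reactions able to produce ``compound_id`` (sorted ids)."""
        return sorted(
            r.id for r in self.reactions.values()
            if compound_id in r.effective_products()
        )

    def consumers(self, compound_id: str) -> list[str]:
        """Reactions able to consume ``compound_id`` (sorted ids)."""
        return sorted(
            r.id for r in self.reactions.values()
            if compound_id in r.effective_substrates()
        )

    def currency_compound_ids(self, currency: Iterable[str] = DEFAULT_CURRENCY) -> set[str]:
        """Ids of compounds whose base name matches the currency list.

        Matching is by compartment-free base name, case-insensitively, so a
        single list entry removes the compound from every compartment.
        """
        names = {c.strip().lower() for c in currency if c.strip()}
        return {
            cid
            for cid, comp in self.compounds.items()
            if comp.base_name.lower() in names or strip_compartment(cid).lower() in names
        }


def strip_compartment(species_id: str) -> str:
    """Drop a trailing ``_<compartment>`` tag (and a leading SBML ``M_``)."""
    sid = species_id
    if sid.startswith("M_"):
        sid = sid[2:]
    if "_" in sid:
        head, tail = sid.rsplit("_", 1)
        if len(tail) <= 2 and head:
            return head
    return sid


# ---------------------------------------------------------------------------
# SBML input/output (via cobra, which wraps libsbml and gene-association rules)
# ---------------------------------------------------------------------------

def parse_sbml(path: str | Path) -> MetabolicNetwork:
    """Parse an SBML reconstruction into a :class:`MetabolicNetwork`.

    All species become compounds; all reactions keep their gene sets
    (flattened from the gene-association rule), substrate/product compound
    ids and reversibility.  Malformed documents raise :class:`SBMLParseError`.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # the model carries no flux objective; silence cobra's reminder
    sbml_logger = logging.getLogger("cobra.io.sbml")
    level = sbml_logger.level
    sbml_logger.setLevel(logging.CRITICAL)  # the reminder is logged at ERROR
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mix of IO/CobraSBMLError types
        raise SBMLParseError(f"cannot parse SBML file {path}: {exc}") from exc
    finally:
        sbml_logger.setLevel(level)
    return network_from_cobra(model)


def network_from_cobra(model) -> MetabolicNetwork:
    """Convert a cobra model into the plain network container."""
    compounds = {
        met.id: Compound(
            id=met.id,
            name=met.name or strip_compartment(met.id),
            compartment=met.compartment or "c",
        )
        for met in model.metabolites
    }
    reactions = {}
    for rxn in model.reactions:
        subs = frozenset(m.id for m, coef in rxn.metabolites.items() if coef < 0)
        prods = frozenset(m.id for m, coef in rxn.metabolites.items() if coef > 0)
        reactions[rxn.id] = Reaction(
            id=rxn.id,
            gene_ids=frozenset(g.id for g in rxn.genes),
            substrates=subs,
            products=prods,
            reversible=bool(rxn.reversibility),
        )
    return MetabolicNetwork(compounds=compounds, reactions=reactions)


def network_to_cobra(net: MetabolicNetwork, model_id: str = "pathscope"):
    """Build a cobra model from a network (used by the SBML writer)."""
    import cobra

    model = cobra.Model(model_id)
    mets = {
        cid: cobra.Metabolite(cid, name=comp.name, compartment=comp.compartment)
        for cid, comp in net.compounds.items()
    }
    cobra_rxns = []
    for rxn in net.reactions.values():
        crx = cobra.Reaction(rxn.id)
        crx.add_metabolites(
            {mets[cid]: -1.0 for cid in rxn.substrates}
            | {mets[cid]: 1.0 for cid in rxn.products}
        )
        crx.lower_bound = -1000.0 if rxn.reversible else 0.0
        crx.upper_bound = 1000.0
        if rxn.gene_ids:
            crx.gene_reaction_rule = " or ".join(sorted(rxn.gene_ids))
        cobra_rxns.append(crx)
    model.add_reactions(cobra_rxns)
    return model


def write_sbml(net: MetabolicNetwork, path: str | Path) -> None:
    """Serialize a network to SBML Level 3 (round-trips via :func:`parse_sbml`)."""
    import cobra.io

    cobra.io.write_sbml_model(network_to_cobra(net), str(path))


# ---------------------------------------------------------------------------
# Expression and metabolite tables
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Gene expression over (condition, time, replicate) columns.

    Stored as a DataFrame whose columns are a MultiIndex
    ``(condition, time, replicate)``; text form is TSV with a header row
    ``id<TAB>condition:time:replicate ...``.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.nlevels != 3:
            raise ValueError("expected (condition, time, replicate) columns")
        data = data.sort_index(axis=1)
        counts = {
            cond: {
                t: len(data.loc[:, (cond, t)].columns)
                for t in data[cond].columns.get_level_values(0).unique()
            }
            for cond in data.columns.get_level_values(0).unique()
        }
        for cond, per_time in counts.items():
            if len(set(per_time.values())) > 1:
                raise ValueError(
                    f"condition {cond!r} has unequal replicate counts per time: {per_time}"
                )
        self.data = data

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data.columns.get_level_values(0).unique())

    def times(self, condition: str) -> list[float]:
        return sorted(self.data[condition].columns.get_level_values(0).unique())

    def n_replicates(self, condition: str) -> int:
        t0 = self.times(condition)[0]
        return len(self.data.loc[:, (condition, t0)].columns)

    def condition_mean(self, condition: str) -> pd.DataFrame:
        """Replicate-averaged profiles: genes x sorted time points."""
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        sub = self.data[condition]
        mean = sub.T.groupby(level=0).mean().T
        return mean[sorted(mean.columns)]

    @classmethod
    def from_tsv(cls, path: str | Path, log2: bool = False) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        cols = []
        for col in frame.columns:
            parts = str(col).split(":")
            if len(parts) != 3:
                raise ValueError(
                    f"column {col!r} is not of the form condition:time:replicate"
                )
            cols.append((parts[0], float(parts[1]), int(parts[2])))
        frame.columns = pd.MultiIndex.from_tuples(
            cols, names=["condition", "time", "replicate"]
        )
        if frame.isna().any().any():
            raise ValueError("expression table contains missing values")
        if log2:
            frame = np.log2(frame)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = [
            f"{c}:{t:g}:{r}" for c, t, r in out.columns
        ]
        out.to_csv(path, sep="\t", index_label="id")


class MetaboliteProfiles(ExpressionMatrix):
    """Metabolite concentrations on the same axes as the expression matrix.

    ``mapping`` sends measured metabolite ids to network compound ids; by
    default each metabolite maps to itself.
    """

    def __init__(self, data: pd.DataFrame, mapping: Mapping[str, str] | None = None):
        super().__init__(data)
        self.mapping = dict(mapping) if mapping else {m: m for m in data.index}

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.index)

    def compound_id(self, metabolite: str) -> str:
        return self.mapping.get(metabolite, metabolite)

    def aligned_with(self, expr: ExpressionMatrix, condition: str) -> bool:
        return self.times(condition) == expr.times(condition)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        mapping_path: str | Path | None = None,
        log2: bool = False,
    ) -> "MetaboliteProfiles":
        base = ExpressionMatrix.from_tsv(path, log2=log2)
        mapping = None
        if mapping_path is not None:
            table = pd.read_csv(
                mapping_path, sep="\t", header=None, names=["metabolite", "compound"]
            )
            mapping = dict(zip(table["metabolite"], table["compound"]))
        return cls(base.data, mapping)


# ---------------------------------------------------------------------------
# Reaction graph construction and weighting
# ---------------------------------------------------------------------------

def build_reaction_graph(
    net: MetabolicNetwork,
    currency: Iterable[str] = DEFAULT_CURRENCY,
) -> nx.DiGraph:
    """Directed reaction-reaction graph with currency edges removed.

    An edge u -> v is drawn for every compound that u can produce and v can
    consume, excluding currency compounds and self-edges.  Reversible
    reactions contribute connectivity in both directions.  Parallel compound
    mediations collapse to one edge; ``compound`` holds one representative
    mediator and ``compounds`` all of them.
    """
    currency_ids = net.currency_compound_ids(currency)
    g = nx.DiGraph()
    g.add_nodes_from(net.reactions)
    produced_by: dict[str, list[str]] = {}
    for rxn in net.reactions.values():
        for cid in rxn.effective_products():
            if cid not in currency_ids:
                produced_by.setdefault(cid, []).append(rxn.id)
    for rxn in net.reactions.values():
        for cid in rxn.effective_substrates():
            if cid in currency_ids:
                continue
            for uid in produced_by.get(cid, ()):
                if uid == rxn.id:
                    continue
                if g.has_edge(uid, rxn.id):
                    g[uid][rxn.id]["compounds"].add(cid)
                else:
                    g.add_edge(uid, rxn.id, compounds={cid})
    for _, _, attrs in g.edges(data=True):
        attrs["compound"] = min(attrs["compounds"])
        attrs["compounds"] = sorted(attrs["compounds"])
    return g


def _standardized_profiles(profiles: pd.DataFrame) -> dict[str, np.ndarray | None]:
    """Per-gene z-scored time profile, or None for zero-variance genes."""
    out: dict[str, np.ndarray | None] = {}
    values = profiles.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    centered = values - means
    sds = centered.std(axis=1)
    for i, gene in enumerate(profiles.index):
        if sds[i] <= 0 or not math.isfinite(sds[i]):
            out[gene] = None
        else:
            out[gene] = centered[i] / sds[i]
    return out


def weight_edges(
    g: nx.DiGraph,
    net: MetabolicNetwork,
    expr: ExpressionMatrix,
    condition: str,
    unmeasured: str = "drop",
) -> nx.DiGraph:
    """Assign each edge the max pairwise gene-expression Pearson correlation.

    Replicates are averaged per time point before correlating.  Edges whose
    endpoint reactions have no measured genes are dropped (``unmeasured=
    'drop'``, counted in the log) or, with ``unmeasured='median'``, given the
    median weight of the measured edges.  Gene pairs with a constant profile
    are skipped; an edge where every pair is skipped is dropped.
    """
    if unmeasured not in {"drop", "median"}:
        raise ValueError("unmeasured must be 'drop' or 'median'")
    profiles = expr.condition_mean(condition)
    n_time = profiles.shape[1]
    if n_time < 3:
        raise ValueError("need at least 3 time points to correlate")
    zprofiles = _standardized_profiles(profiles)
    measured = set(profiles.index)

    def reaction_profiles(rid: str) -> list[np.ndarray]:
        vecs = []
        for gene in sorted(net.reactions[rid].gene_ids & measured):
            z = zprofiles[gene]
            if z is not None:
                vecs.append(z)
        return vecs

    cache = {rid: reaction_profiles(rid) for rid in g.nodes}
    weighted = nx.DiGraph()
    weighted.add_nodes_from(g.nodes(data=True))
    n_dropped = 0
    deferred = []
    for u, v, attrs in g.edges(data=True):
        pu, pv = cache[u], cache[v]
        if not pu or not pv:
            n_dropped += 1
            if unmeasured == "median":
                deferred.append((u, v, attrs))
            continue
        # max over all gene pairs of the Pearson correlation
        corr = np.asarray(pu) @ np.asarray(pv).T / n_time
        w = float(np.clip(corr.max(), -1.0, 1.0))
        weighted.add_edge(u, v, weight=w, **attrs)
    if deferred and weighted.number_of_edges():
        med = float(np.median([d["weight"] for _, _, d in weighted.edges(data=True)]))
        for u, v, attrs in deferred:
            weighted.add_edge(u, v, weight=med, **attrs)
    if n_dropped:
        logger.info(
            "%d edges had an endpoint with no measured genes (%s)",
            n_dropped,
            "assigned median weight" if unmeasured == "median" else "dropped",
        )
    return weighted


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def write_graph(g: nx.DiGraph, path: str | Path, fmt: str | None = None) -> None:
    """Write a reaction graph as GraphML or 3-column TSV (source, target, weight)."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "tsv")
    if fmt == "graphml":
        out = nx.DiGraph()
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            attrs = {k: v2 for k, v2 in d.items() if not isinstance(v2, (list, set))}
            if "compounds" in d:
                attrs["compounds"] = ",".join(d["compounds"])
            out.add_edge(u, v, **attrs)
        nx.write_graphml(out, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('weight', float('nan')):.10g}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_weighted_graph_tsv(path: str | Path) -> nx.DiGraph:
    """Read a 3-column TSV weighted graph written by :func:`write_graph`."""
    frame = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for row in frame.itertuples(index=False):
        g.add_edge(str(row.source), str(row.target), weight=float(row.weight))
    return g
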