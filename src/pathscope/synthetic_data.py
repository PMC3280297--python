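"""Synthetic networks, expression and metabolite profiles with known truth.

The generator emulates the structure of a stress time-course study on a
genome-scale reconstruction at toy scale: a bipartite compound-reaction
network with gene sets per reaction, replicated time-course expression with
planted chains of highly correlated reactions, and metabolite profiles
coupled to the expression of a planted hub reaction.

Planted design.  Each of ``n_chains`` source compounds feeds a linear main
chain of ``chain_length`` reactions; all main chains converge on one shared
terminal hub reaction that produces ``n_hub_products`` final compounds.
Each source additionally feeds a private spur chain, which makes the source
the only compound whose scope spans both of its branches — so the planted
sources form the unique minimum scope cover under the design conditions.
Background reactions wire the remaining compounds at random; they may
consume planted compounds (downstream leakage, as in a real network) but
never produce them, preserving the sources' seed-compound role.  Genes of
all planted reactions form one high-correlation module (pairwise rho_in);
everything else correlates at rho_out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network_model import (
    Compound,
    ExpressionMatrix,
    MetabolicNetwork,
    MetaboliteProfiles,
    Reaction,
    write_sbml,
)

logger = logging.getLogger(__name__)

CONDITION = "synthetic"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of the synthetic generator.

    Defaults follow the stress time-course design the package targets:
    8 time points with 3 biological replicates, three planted source
    metabolites with within-module gene correlation 0.95 against a 0.05
    background, and a network sized so the edge-weight ECDF resolves the
    Bonferroni threshold (60 compounds, 125 reactions, one gene each).
    """

    n_compounds: int = 72
    n_background_reactions: int = 120
    n_chains: int = 3
    chain_length: int = 4  # main-chain reactions per source (before the hub)
    spur_length: int = 4  # private spur reactions per source
    n_hub_products: int = 3
    genes_per_reaction: tuple[int, int] = (2, 2)  # background reactions
    planted_genes: int = 3  # genes per planted chain/spur reaction
    hub_genes_per_chain: int = 2
    dedicated_fin_consumers: int = 4  # satellite-producing consumers per hub product
    bg_substrates: int = 2
    bg_products: int = 2
    n_time: int = 8
    n_replicates: int = 3
    rho_in: float = 0.95
    rho_out: float = 0.05
    rho_m: float = 0.9  # hub-metabolite coupling
    noise_sd: float = 0.25
    currency_fraction: float = 0.3
    n_uncoupled_metabolites: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rho_out < self.rho_in <= 1.0:
            raise ValueError("need rho_out < rho_in <= 1")
        if self.n_planted_compounds >= self.n_compounds:
            raise ValueError(
                f"{self.n_compounds} compounds cannot hold "
                f"{self.n_planted_compounds} planted ones"
            )

    @property
    def n_planted_compounds(self) -> int:
        return (
            self.n_chains * (1 + self.chain_length + self.spur_length)
            + self.n_hub_products
            + self.n_satellites
        )

    @property
    def n_satellites(self) -> int:
        return self.n_hub_products * self.dedicated_fin_consumers

    @property
    def sources(self) -> list[str]:
        return [f"src{k}_c" for k in range(1, self.n_chains + 1)]

    @property
    def hub_reaction(self) -> str:
        return "HUB"

    @property
    def hub_products(self) -> list[str]:
        return [f"fin{i}_c" for i in range(1, self.n_hub_products + 1)]


@dataclass
class GroundTruth:
    """What was planted: sources, chains, hub and coupled metabolites."""

    sources: list[str]
    main_chains: dict[str, list[str]]  # source -> main-chain reactions (+hub)
    spur_chains: dict[str, list[str]]
    hub_reaction: str
    hub_products: list[str]
    coupled_metabolites: list[str]
    module_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _rng(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def generate_network(spec: SyntheticSpec) -> tuple[MetabolicNetwork, GroundTruth]:
    """Random bipartite network with the planted chains embedded.

    Deterministic under ``spec.seed``; the planted chains are valid directed
    reaction chains of the generated network by construction, and currency
    attachments (ATP/H2O on a random reaction fraction) only add edges that
    preprocessing must remove.
    """
    rng = _rng(spec, 1)
    compounds: dict[str, Compound] = {}

    def add_compound(cid: str) -> str:
        base = cid[:-2] if cid.endswith("_c") else cid
        compounds[cid] = Compound(id=cid, name=base, compartment="c")
        return cid

    for cid in spec.sources:
        add_compound(cid)
    for cid in spec.hub_products:
        add_compound(cid)
    main_int = {
        src: [add_compound(f"m{k}_{j}_c") for j in range(1, spec.chain_length + 1)]
        for k, src in enumerate(spec.sources, start=1)
    }
    spur_int = {
        src: [add_compound(f"z{k}_{j}_c") for j in range(1, spec.spur_length + 1)]
        for k, src in enumerate(spec.sources, start=1)
    }
    n_bg = spec.n_compounds - spec.n_planted_compounds
    bg_compounds = [add_compound(f"bg{i:03d}_c") for i in range(1, n_bg + 1)]
    currency = {"atp_c": "ATP", "h2o_c": "H2O"}
    for cid, name in currency.items():
        compounds[cid] = Compound(id=cid, name=name, compartment="c")

    reactions: dict[str, Reaction] = {}
    gene_counter = 0

    def genes_for(rid: str) -> frozenset[str]:
        nonlocal gene_counter
        lo, hi = spec.genes_per_reaction
        k = int(rng.integers(lo, hi + 1))
        ids = []
        for _ in range(k):
            gene_counter += 1
            ids.append(f"g{gene_counter:04d}")
        return frozenset(ids)

    def add_reaction(
        rid: str, subs: set[str], prods: set[str], n_genes: int | None = None
    ) -> None:
        nonlocal gene_counter
        draw = rng.random()
        if draw < spec.currency_fraction:
            # ATP-consuming or ATP-regenerating attachment, so currency
            # compounds are both produced and consumed across the network
            if draw < spec.currency_fraction / 2:
                subs, prods = subs | {"atp_c"}, prods | {"h2o_c"}
            else:
                subs, prods = subs | {"h2o_c"}, prods | {"atp_c"}
        if n_genes is None:
            genes = genes_for(rid)
        else:
            ids = []
            for _ in range(n_genes):
                gene_counter += 1
                ids.append(f"g{gene_counter:04d}")
            genes = frozenset(ids)
        reactions[rid] = Reaction(
            id=rid,
            gene_ids=genes,
            substrates=frozenset(subs),
            products=frozenset(prods),
            reversible=False,
        )

    main_chains: dict[str, list[str]] = {}
    spur_chains: dict[str, list[str]] = {}
    for k, src in enumerate(spec.sources, start=1):
        chain = []
        prev = src
        for j, inter in enumerate(main_int[src], start=1):
            rid = f"R{k}M{j}"
            add_reaction(rid, {prev}, {inter}, n_genes=spec.planted_genes)
            chain.append(rid)
            prev = inter
        main_chains[src] = chain + [spec.hub_reaction]
        spur = []
        prev = src
        for j, inter in enumerate(spur_int[src], start=1):
            rid = f"R{k}S{j}"
            add_reaction(rid, {prev}, {inter}, n_genes=spec.planted_genes)
            spur.append(rid)
            prev = inter
        spur_chains[src] = spur
    # the hub carries genes of every converging chain, so each incoming edge
    # pairs the chain's last reaction with hub genes of that chain's process
    add_reaction(
        spec.hub_reaction,
        {main_int[src][-1] for src in spec.sources},
        set(spec.hub_products),
        n_genes=spec.n_chains * spec.hub_genes_per_chain,
    )

    # background reactions: substrates may tap planted compounds (but never
    # the sources), products stay within the background pool
    substrate_pool = sorted(
        set(bg_compounds)
        | {c for lst in main_int.values() for c in lst}
        | {c for lst in spur_int.values() for c in lst}
        | set(spec.hub_products)
    )
    # satellite reactions consume the hub products and produce compounds with
    # no other producer, making the hub a high-traffic junction whose
    # witness paths cannot be rerouted through the background
    dedicated = [
        fin
        for fin in spec.hub_products
        for _ in range(spec.dedicated_fin_consumers)
    ]
    for i, fin in enumerate(dedicated, start=1):
        add_compound(f"sat{i:02d}_c")
        add_reaction(f"SAT{i:02d}", {fin}, {f"sat{i:02d}_c"})
    for i in range(1, spec.n_background_reactions + 1):
        rid = f"BG{i:03d}"
        subs = set(
            rng.choice(substrate_pool, size=spec.bg_substrates, replace=False)
        )
        prod_pool = [c for c in bg_compounds if c not in subs]
        prods = set(rng.choice(prod_pool, size=spec.bg_products, replace=False))
        add_reaction(rid, subs, prods)

    net = MetabolicNetwork(compounds=compounds, reactions=reactions)
    planted = (
        [r for c in main_chains.values() for r in c]
        + [r for c in spur_chains.values() for r in c]
    )
    module_genes = sorted(
        {g for rid in set(planted) for g in reactions[rid].gene_ids}
    )
    truth = GroundTruth(
        sources=list(spec.sources),
        main_chains=main_chains,
        spur_chains=spur_chains,
        hub_reaction=spec.hub_reaction,
        hub_products=list(spec.hub_products),
        coupled_metabolites=list(spec.hub_products),
        module_genes=module_genes,
    )
    return net, truth


def _repair_correlation(c: np.ndarray) -> np.ndarray:
    """Nearest-PD-style repair: clip eigenvalues, rescale to unit diagonal."""
    eigval, eigvec = np.linalg.eigh(c)
    if eigval.min() > 1e-10:
        return c
    clipped = np.clip(eigval, 1e-8, None)
    repaired = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    # mild conflicts (several genes per chain position cannot satisfy the
    # exact first-order structure) are expected and repaired quietly
    log = logger.warning if eigval.min() < -0.05 else logger.debug
    log(
        "requested correlation matrix was not positive definite "
        "(min eigenvalue %.3g); repaired by eigenvalue clipping", eigval.min()
    )
    return repaired


def _branch_positions(
    net: MetabolicNetwork, truth: GroundTruth
) -> list[dict[str, int]]:
    """Per planted branch: gene -> position along the reaction sequence.

    Each source's main chain (hub included) and private spur form separate
    branches.  The hub contributes one gene per chain, assigned in sorted
    order to the sorted sources, so every converging edge stays within one
    branch process.
    """
    hub_genes = sorted(net.reactions[truth.hub_reaction].gene_ids)
    chains = sorted(truth.main_chains)
    per_chain = max(1, len(hub_genes) // len(chains))
    branches = []
    for i, src in enumerate(chains):
        chain = truth.main_chains[src]
        pos: dict[str, int] = {}
        for j, rid in enumerate(chain[:-1]):  # all but the hub
            for gene in net.reactions[rid].gene_ids:
                pos[gene] = j
        for gene in hub_genes[i * per_chain : (i + 1) * per_chain]:
            pos[gene] = len(chain) - 1
        branches.append(pos)
    for src in sorted(truth.spur_chains):
        pos = {}
        for j, rid in enumerate(truth.spur_chains[src]):
            for gene in net.reactions[rid].gene_ids:
                pos[gene] = j
        branches.append(pos)
    return branches


def target_correlation(
    spec: SyntheticSpec, net: MetabolicNetwork, truth: GroundTruth
) -> tuple[list[str], np.ndarray]:
    """Gene list and the requested gene-gene correlation matrix.

    Within a planted branch the correlation decays geometrically with the
    number of reaction steps separating two genes — exactly rho_in for
    genes of the same or of consecutive reactions — with a rho_out floor;
    all remaining pairs sit at rho_out.  The local (first-order Markov)
    structure is positive definite without repair and keeps sampling
    fluctuations of different chain edges nearly independent.
    """
    genes = sorted({g for r in net.reactions.values() for g in r.gene_ids})
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    c = np.full((n, n), spec.rho_out)
    for pos in _branch_positions(net, truth):
        members = sorted(pos)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ga, gb = members[a], members[b]
                d = max(1, abs(pos[ga] - pos[gb]))
                val = max(spec.rho_out, spec.rho_in**d)
                i, j = idx[ga], idx[gb]
                c[i, j] = c[j, i] = max(c[i, j], val)
    np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() <= 1e-10:
        c = _repair_correlation(c)
    return genes, c


def generate_expression(
    spec: SyntheticSpec, net: MetabolicNetwork, truth: GroundTruth
) -> ExpressionMatrix:
    """Time-course expression with the planted correlation structure.

    Latent profiles are ``n_time`` draws from N(0, C); replicates add iid
    N(0, noise_sd^2) measurement noise around the latent profile.
    """
    rng = _rng(spec, 2)
    genes, c = target_correlation(spec, net, truth)
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix not positive definite") from exc
    latent = (chol @ rng.standard_normal((len(genes), spec.n_time)))
    cols = {}
    for t in range(spec.n_time):
        for rep in range(1, spec.n_replicates + 1):
            noise = spec.noise_sd * rng.standard_normal(len(genes))
            cols[(CONDITION, float(t), rep)] = latent[:, t] + noise
    frame = pd.DataFrame(cols, index=genes)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["condition", "time", "replicate"]
    )
    return ExpressionMatrix(frame)


def generate_metabolites(
    spec: SyntheticSpec,
    net: MetabolicNetwork,
    truth: GroundTruth,
    expr: ExpressionMatrix,
) -> MetaboliteProfiles:
    """Metabolite profiles: hub-coupled targets plus iid-noise controls.

    Coupled metabolites follow rho_m * z(hub mean expression) plus scaled
    noise (z-scaled again); uncoupled metabolites (the sources and the first
    background compounds) are pure noise.
    """
    rng = _rng(spec, 3)
    profiles = expr.condition_mean(CONDITION)
    hub_genes = sorted(net.reactions[truth.hub_reaction].gene_ids)
    hub_mean = profiles.loc[hub_genes].mean(axis=0).to_numpy()
    hub_z = (hub_mean - hub_mean.mean()) / hub_mean.std()

    def coupled_profile() -> np.ndarray:
        noise = rng.standard_normal(spec.n_time)
        raw = spec.rho_m * hub_z + np.sqrt(1 - spec.rho_m**2) * noise
        return (raw - raw.mean()) / raw.std()

    bg = sorted(
        c for c in net.compounds
        if c.startswith("bg")
    )[: spec.n_uncoupled_metabolites]
    latent = {}
    for cid in truth.coupled_metabolites:
        latent[cid] = coupled_profile()
    for cid in list(truth.sources) + bg:
        latent[cid] = rng.standard_normal(spec.n_time)
    cols = {}
    ids = sorted(latent)
    for t in range(spec.n_time):
        for rep in range(1, spec.n_replicates + 1):
            noise = spec.noise_sd * rng.standard_normal(len(ids))
            cols[(CONDITION, float(t), rep)] = np.array(
                [latent[cid][t] for cid in ids]
            ) + noise
    frame = pd.DataFrame(cols, index=ids)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["condition", "time", "replicate"]
    )
    return MetaboliteProfiles(frame, mapping={cid: cid for cid in ids})


@dataclass
class StudyData:
    """A complete generated study: network, truth, expression, metabolites."""

    spec: SyntheticSpec
    network: MetabolicNetwork
    truth: GroundTruth
    expression: ExpressionMatrix
    metabolites: MetaboliteProfiles


def generate_study(spec: SyntheticSpec) -> StudyData:
    net, truth = generate_network(spec)
    expr = generate_expression(spec, net, truth)
    metab = generate_metabolites(spec, net, truth, expr)
    return StudyData(
        spec=spec, network=net, truth=truth, expression=expr, metabolites=metab
    )


def write_study(study: StudyData, out_dir: str | Path) -> None:
    """SBML + expression TSV + metabolite TSV + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sbml(study.network, out / "network.xml")
    study.expression.to_tsv(out / "expression.tsv")
    study.metabolites.to_tsv(out / "metabolites.tsv")
    study.truth.to_json(out / "truth.json")
    (out / "spec.json").write_text(
        json.dumps(dataclasses.asdict(study.spec), indent=2)
    )
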