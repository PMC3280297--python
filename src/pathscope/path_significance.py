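"""Path scoring and significance on the weighted reaction graph.

A path between two compounds is an ordered sequence of reactions; its L
edge weights are ranked against all edge weights of the network through the
empirical distribution of weights.  Writing u_i for the upper-tail
probability of edge i (the fraction of network edges at least as heavily
weighted), the path score is

    score = -sum_i ln u_i  >= 0          (higher = more extreme)

and with q = prod_i u_i = exp(-score) the closed-form p-value is the chance
that L edge weights drawn randomly and independently from the network
distribution are jointly at least as extreme:

    p = P(prod_i U_i <= q) = q * sum_{k<L} (-ln q)^k / k!,   U_i ~ U(0,1)

which equals the upper tail of a Gamma(L, 1) variable at -ln q.  Ranking by
p rather than by score removes the bias toward short paths: at fixed length
minimizing p is the same as maximizing the score, so a dynamic program that
extracts the best path at every length 1..Lmax, followed by direct
evaluation of p, yields the most significant path overall.

Because network edges are not independent draws, an empirical alternative
samples paths from the network itself (Metropolis within each length
stratum) and uses their closed-form p-values as a reference distribution.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import special

__all__ = [
    "EdgeWeightECDF",
    "Path",
    "ReferenceDistribution",
    "fit_ecdf",
    "path_score",
    "pvalue_closed",
    "pvalue_empirical",
    "PathDP",
    "best_paths_all_lengths",
    "metropolis_sample",
    "most_significant_path",
]


class EdgeWeightECDF:
    """Empirical distribution of the edge weights of a weighted graph.

    ``cdf(w)`` is the right-closed lower tail #{weights <= w}/m, so the
    network maximum evaluates to 1 and no observed weight evaluates to 0.
    ``upper(w)`` is the mirrored tail #{weights >= w}/m used for path
    significance; it is likewise never 0 for an observed weight, keeping
    logarithms finite.
    """

    def __init__(self, weights: Iterable[float]):
        arr = np.sort(np.asarray(list(weights), dtype=float))
        if arr.size == 0:
            raise ValueError("cannot fit an ECDF on an empty weight set")
        if np.isnan(arr).any():
            raise ValueError("edge weights contain NaN")
        self.weights = arr
        self.m = arr.size

    def cdf(self, w):
        """F(w) = #{weights <= w} / m."""
        return np.searchsorted(self.weights, w, side="right") / self.m

    __call__ = cdf

    def upper(self, w):
        """u(w) = #{weights >= w} / m (the significance tail)."""
        return (self.m - np.searchsorted(self.weights, w, side="left")) / self.m


def fit_ecdf(g: nx.DiGraph) -> EdgeWeightECDF:
    """ECDF over all edge weights of a weighted reaction graph."""
    weights = [d["weight"] for _, _, d in g.edges(data=True) if "weight" in d]
    if not weights:
        raise ValueError("graph has no weighted edges")
    return EdgeWeightECDF(weights)


@dataclass(frozen=True)
class Path:
    """A scored reaction path between two pseudo-attached compound ends."""

    reactions: tuple[str, ...]
    weights: tuple[float, ...]
    score: float
    q: float
    p_closed: float
    p_empirical: float | None = None
    source: str | None = None
    target: str | None = None

    @property
    def length(self) -> int:
        """Number of weighted reaction-reaction edges."""
        return len(self.weights)

    @property
    def p(self) -> float:
        """The p-value used for ranking (empirical when available)."""
        return self.p_empirical if self.p_empirical is not None else self.p_closed

    def is_simple(self) -> bool:
        return len(set(self.reactions)) == len(self.reactions)


def path_score(weights: Sequence[float], ecdf: EdgeWeightECDF) -> float:
    """score = -sum ln u(w_i); additive over concatenation, 0 for empty."""
    u = ecdf.upper(np.asarray(weights, dtype=float))
    if np.any(u <= 0):
        raise ValueError("path contains a weight above the network maximum")
    return float(-np.log(u).sum())


def pvalue_closed(q: float, length: int) -> float:
    """p = q * sum_{k<L} (-ln q)^k / k! = P(Gamma(L,1) >= -ln q).

    The probability that a product of ``length`` independent Uniform(0,1)
    variables is at most ``q``; strictly increasing in q, equal to q at
    L = 1 and to 1 at q = 1.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    if length < 1:
        raise ValueError(f"path length must be >= 1, got {length}")
    return float(special.gammaincc(length, -math.log(q)))


@dataclass
class ReferenceDistribution:
    """Metropolis-sampled path products, the empirical null for p-values."""

    q_by_length: dict[int, np.ndarray]
    seed: int
    acceptance_rate: float
    p_closed_sorted: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ps = [
            special.gammaincc(length, -np.log(qs))
            for length, qs in self.q_by_length.items()
            if len(qs)
        ]
        self.p_closed_sorted = (
            np.sort(np.concatenate(ps)) if ps else np.empty(0)
        )

    @property
    def n(self) -> int:
        return int(self.p_closed_sorted.size)

    def lengths(self) -> list[int]:
        return sorted(self.q_by_length)

    def save(self, path: str | FilePath) -> None:
        payload = {f"q_{length}": qs for length, qs in self.q_by_length.items()}
        np.savez(
            path,
            seed=self.seed,
            acceptance_rate=self.acceptance_rate,
            **payload,
        )

    @classmethod
    def load(cls, path: str | FilePath) -> "ReferenceDistribution":
        with np.load(path) as data:
            q_by_length = {
                int(k[2:]): data[k] for k in data.files if k.startswith("q_")
            }
            return cls(
                q_by_length=q_by_length,
                seed=int(data["seed"]),
                acceptance_rate=float(data["acceptance_rate"]),
            )


def pvalue_empirical(path: Path, ref: ReferenceDistribution) -> float:
    """Pooled empirical p: (1 + #{reference p <= path p}) / (1 + N).

    The closed form already normalizes for length, so reference paths of all
    lengths are pooled; the add-one keeps the result in [1/(1+N), 1].
    """
    if ref.n == 0:
        raise ValueError("reference distribution is empty")
    count = int(np.searchsorted(ref.p_closed_sorted, path.p_closed, side="right"))
    return (1 + count) / (1 + ref.n)


# ---------------------------------------------------------------------------
# Dynamic program: best path at every length
# ---------------------------------------------------------------------------

_NEG_INF = float("-inf")


class PathDP:
    """Best-scoring walk of every length from a fixed source reaction set.

    The recurrence runs over edge states (the walk's last edge), which
    forbids immediate backtracking u -> v -> u; node revisits further back
    are allowed and filtered at reconstruction.  One table serves every
    target set, so a compound's whole scope reuses a single forward pass.
    Ties are broken deterministically toward the predecessor edge with the
    lexicographically smallest source reaction.
    """

    def __init__(
        self,
        g: nx.DiGraph,
        ecdf: EdgeWeightECDF,
        source_reactions: Iterable[str],
        lmax: int,
    ):
        if lmax < 1:
            raise ValueError("lmax must be >= 1")
        self.lmax = lmax
        self.sources = frozenset(source_reactions)
        edges = sorted(g.edges(data="weight"))
        self.edge_src = [u for u, _, _ in edges]
        self.edge_dst = [v for _, v, _ in edges]
        weights = np.array([w for _, _, w in edges], dtype=float)
        self.edge_weight = weights
        with np.errstate(divide="raise"):
            self.edge_gain = -np.log(ecdf.upper(weights))  # >= 0, finite
        self.n_edges = len(edges)
        self.in_edges: dict[str, list[int]] = {}
        for idx, v in enumerate(self.edge_dst):
            self.in_edges.setdefault(v, []).append(idx)
        self.edges_into: dict[str, list[int]] = self.in_edges
        self._run()

    def _run(self) -> None:
        n = self.n_edges
        best = np.full(n, _NEG_INF)
        back = np.full(n, -1, dtype=np.int64)
        for e in range(n):
            if self.edge_src[e] in self.sources:
                best[e] = self.edge_gain[e]
        self.best = [best]
        self.back = [back]
        for _ in range(2, self.lmax + 1):
            prev = self.best[-1]
            # per destination node: best and best-with-distinct-source
            # predecessor edge among edges entering that node
            node_top: dict[str, tuple[float, str, int, float, int]] = {}
            for v, idxs in self.in_edges.items():
                b_val, b_src, b_idx = _NEG_INF, "", -1
                a_val, a_idx = _NEG_INF, -1  # best with src != b_src
                for e in idxs:
                    val = prev[e]
                    if val == _NEG_INF:
                        continue
                    src = self.edge_src[e]
                    if val > b_val:
                        if b_idx >= 0 and b_src != src and b_val > a_val:
                            a_val, a_idx = b_val, b_idx
                        b_val, b_src, b_idx = val, src, e
                    elif src != b_src and val > a_val:
                        a_val, a_idx = val, e
                if b_idx >= 0:
                    node_top[v] = (b_val, b_src, b_idx, a_val, a_idx)
            cur = np.full(n, _NEG_INF)
            backs = np.full(n, -1, dtype=np.int64)
            for e in range(n):
                top = node_top.get(self.edge_src[e])
                if top is None:
                    continue
                b_val, b_src, b_idx, a_val, a_idx = top
                if b_src == self.edge_dst[e]:  # would backtrack
                    b_val, b_idx = a_val, a_idx
                if b_idx >= 0:
                    cur[e] = b_val + self.edge_gain[e]
                    backs[e] = b_idx
            self.best.append(cur)
            self.back.append(backs)

    def terminal_edges(self, target_reactions: Iterable[str]) -> list[int]:
        targets = set(target_reactions)
        return [e for e in range(self.n_edges) if self.edge_dst[e] in targets]

    def best_score(self, length: int, terminal: Sequence[int]) -> tuple[float, int]:
        """(score, terminal edge) of the best length-``length`` walk, or -inf."""
        table = self.best[length - 1]
        b_val, b_idx = _NEG_INF, -1
        for e in terminal:
            if table[e] > b_val:
                b_val, b_idx = table[e], e
        return b_val, b_idx

    def walk_scores(self, terminal: Sequence[int]) -> dict[int, float]:
        """Best walk score per length (unfiltered), lengths with a walk only."""
        out = {}
        for length in range(1, self.lmax + 1):
            val, _ = self.best_score(length, terminal)
            if val > _NEG_INF:
                out[length] = float(val)
        return out

    def reconstruct(self, length: int, edge: int) -> tuple[list[str], list[float]]:
        nodes = [self.edge_dst[edge]]
        weights = []
        e = edge
        for level in range(length - 1, -1, -1):
            weights.append(float(self.edge_weight[e]))
            nodes.append(self.edge_src[e])
            e = int(self.back[level][e])
        nodes.reverse()
        weights.reverse()
        return nodes, weights

    def ranked_terminals(self, length: int, terminal: Sequence[int]) -> list[int]:
        table = self.best[length - 1]
        live = [e for e in terminal if table[e] > _NEG_INF]
        return sorted(live, key=lambda e: (-table[e], e))


def _make_path(
    reactions: Sequence[str],
    weights: Sequence[float],
    ecdf: EdgeWeightECDF,
    ref: ReferenceDistribution | None = None,
    source: str | None = None,
    target: str | None = None,
) -> Path:
    score = path_score(weights, ecdf)
    q = float(np.exp(-score))
    p_closed = pvalue_closed(q, len(weights))
    path = Path(
        reactions=tuple(reactions),
        weights=tuple(weights),
        score=score,
        q=q,
        p_closed=p_closed,
        source=source,
        target=target,
    )
    if ref is not None:
        path = dataclasses.replace(path, p_empirical=pvalue_empirical(path, ref))
    return path


def best_paths_all_lengths(
    g: nx.DiGraph,
    ecdf: EdgeWeightECDF,
    source_reactions: Iterable[str],
    target_reactions: Iterable[str],
    lmax: int,
    ref: ReferenceDistribution | None = None,
    max_reconstruct: int = 10,
    dp: PathDP | None = None,
    source: str | None = None,
    target: str | None = None,
) -> list[Path]:
    """Best simple path per length 1..lmax between two reaction sets.

    For each length the dynamic program's best walks are reconstructed in
    score order until a simple one is found (at most ``max_reconstruct``
    attempts); lengths without a simple walk are absent.
    """
    if dp is None:
        dp = PathDP(g, ecdf, source_reactions, lmax)
    terminal = dp.terminal_edges(target_reactions)
    paths = []
    for length in range(1, lmax + 1):
        for e in dp.ranked_terminals(length, terminal)[:max_reconstruct]:
            nodes, weights = dp.reconstruct(length, e)
            if len(set(nodes)) == len(nodes):
                paths.append(
                    _make_path(nodes, weights, ecdf, ref, source, target)
                )
                break
    return paths


def most_significant_path(
    g: nx.DiGraph,
    ecdf: EdgeWeightECDF,
    source_reactions: Iterable[str],
    target_reactions: Iterable[str],
    lmax: int,
    ref: ReferenceDistribution | None = None,
    **kwargs,
) -> Path | None:
    """The minimum-p path over all lengths; None when no path exists.

    Ties are broken toward the shorter path, then lexicographic reaction
    order.  With a reference distribution supplied the empirical p-value is
    used for ranking, otherwise the closed form.
    """
    candidates = best_paths_all_lengths(
        g, ecdf, source_reactions, target_reactions, lmax, ref=ref, **kwargs
    )
    if not candidates:
        return None
    return min(candidates, key=lambda p: (p.p, p.length, p.reactions))


# ---------------------------------------------------------------------------
# Metropolis path sampling
# ---------------------------------------------------------------------------

class _WalkSpace:
    """Per-node out-edge tables for weighted random-walk proposals."""

    def __init__(self, g: nx.DiGraph, ecdf: EdgeWeightECDF):
        self.succ: dict[str, list[str]] = {}
        self.probs: dict[str, np.ndarray] = {}
        self.logu: dict[str, dict[str, float]] = {}
        self.logz: dict[str, float] = {}
        for u in sorted(g.nodes):
            nbrs = sorted(g.successors(u))
            if not nbrs:
                continue
            uvals = np.array(
                [ecdf.upper(g[u][v]["weight"]) for v in nbrs], dtype=float
            )
            z = uvals.sum()
            self.succ[u] = nbrs
            self.probs[u] = uvals / z
            self.logz[u] = math.log(z)
            self.logu[u] = {
                v: math.log(uv) for v, uv in zip(nbrs, uvals)
            }
        self.nodes = sorted(self.succ)

    def grow(self, start: str, steps: int, rng: np.random.Generator):
        """Weighted random walk; returns (nodes_after_start, log_proposal,
        log_q) or None at a dead end."""
        nodes, logp, logq = [], 0.0, 0.0
        cur = start
        for _ in range(steps):
            nbrs = self.succ.get(cur)
            if not nbrs:
                return None
            i = int(rng.choice(len(nbrs), p=self.probs[cur]))
            nxt = nbrs[i]
            step_logu = self.logu[cur][nxt]
            logp += step_logu - self.logz[cur]
            logq += step_logu
            nodes.append(nxt)
            cur = nxt
        return nodes, logp, logq

    def walk_density(self, nodes: Sequence[str], start_at: int):
        """(log proposal density, log q) of the stored walk from position
        ``start_at`` onward."""
        logp, logq = 0.0, 0.0
        for i in range(start_at, len(nodes) - 1):
            u, v = nodes[i], nodes[i + 1]
            step_logu = self.logu[u][v]
            logp += step_logu - self.logz[u]
            logq += step_logu
        return logp, logq


def metropolis_sample(
    g: nx.DiGraph,
    ecdf: EdgeWeightECDF,
    lmax: int,
    n_samples: int,
    seed: int,
    bias: float = 0.0,
    burn_in: int = 1000,
    thin: int = 25,
    n_chains: int = 5,
    min_per_length: int = 10,
) -> ReferenceDistribution:
    """Sample walks of every length 1..lmax as a reference distribution.

    Within each length stratum a Metropolis chain targets the uniform
    distribution over walks of that length (``bias`` tilts the target by
    (prod u_i)^bias for the weighted variant).  Proposals mix suffix
    regrowth from a uniformly chosen cut point with full restarts from a
    uniformly chosen node (so the chain moves its start); steps are drawn
    with probability proportional to the upper-tail edge probability and
    the Metropolis ratio corrects the proposal bias.  Strata with no walk
    are recorded empty with a warning.  Sampled products q are stored per
    length; reproducible under ``seed``.
    """
    import warnings

    if n_samples < min_per_length * lmax:
        raise ValueError(
            f"need at least {min_per_length} samples per length "
            f"({min_per_length * lmax} total), got {n_samples}"
        )
    rng = np.random.default_rng(seed)
    space = _WalkSpace(g, ecdf)
    per_length = np.full(lmax, n_samples // lmax, dtype=int)
    per_length[: n_samples - per_length.sum()] += 1
    q_by_length: dict[int, np.ndarray] = {}
    accepted = proposed = 0
    for length, n_l in zip(range(1, lmax + 1), per_length):
        # several independent chains per stratum keep autocorrelation out of
        # the empirical distribution
        chunk = [n_l // n_chains] * n_chains
        for i in range(n_l - sum(chunk)):
            chunk[i] += 1
        collected: list[np.ndarray] = []
        for n_c in chunk:
            if n_c == 0:
                continue
            out = _run_chain(
                space, length, n_c, rng, bias, burn_in, thin
            )
            if out is None:
                break
            collected.append(out[0])
            accepted += out[1]
            proposed += out[2]
        if not collected:
            warnings.warn(f"no walk of length {length}; stratum left empty")
            q_by_length[length] = np.empty(0)
            continue
        q_by_length[length] = np.concatenate(collected)
    rate = accepted / proposed if proposed else 1.0
    return ReferenceDistribution(
        q_by_length=q_by_length, seed=seed, acceptance_rate=rate
    )


def _run_chain(
    space: _WalkSpace,
    length: int,
    n_samples: int,
    rng: np.random.Generator,
    bias: float,
    burn_in: int,
    thin: int,
):
    """One Metropolis chain over walks of a fixed length; None if no walk."""
    state = None
    for _ in range(200):
        if not space.nodes:
            break
        start = space.nodes[int(rng.integers(len(space.nodes)))]
        grown = space.grow(start, length, rng)
        if grown is not None:
            state = [start] + grown[0]
            break
    if state is None:
        return None
    _, state_logq = space.walk_density(state, 0)
    samples = np.empty(n_samples)
    accepted = proposed = 0
    got = 0
    it = 0
    restart_prob = 0.5
    while got < n_samples:
        it += 1
        proposed += 1
        if rng.random() < restart_prob:
            # independence proposal: fresh walk from a random start
            start = space.nodes[int(rng.integers(len(space.nodes)))]
            grown = space.grow(start, length, rng)
            if grown is not None:
                cand = [start] + grown[0]
                prop_logp = grown[1]
                rev_logp, _ = space.walk_density(state, 0)
                cand_logq = grown[2]
                log_alpha = (
                    bias * (cand_logq - state_logq) + rev_logp - prop_logp
                )
                if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                    state, state_logq = cand, cand_logq
                    accepted += 1
        else:
            cut = int(rng.integers(length))
            grown = space.grow(state[cut], length - cut, rng)
            if grown is not None:
                new_nodes, prop_logp, _ = grown
                cand = state[: cut + 1] + new_nodes
                rev_logp, _ = space.walk_density(state, cut)
                _, cand_logq = space.walk_density(cand, 0)
                log_alpha = (
                    bias * (cand_logq - state_logq) + rev_logp - prop_logp
                )
                if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                    state, state_logq = cand, cand_logq
                    accepted += 1
        if it > burn_in and (it - burn_in) % thin == 0:
            samples[got] = math.exp(state_logq)
            got += 1
    return samples, accepted, proposed
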