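"""Minimum set cover over metabolite scopes, as a binary integer program.

Choose the fewest scopes whose union contains every compound reachable by
any significant path:

    min sum_j x_j   s.t.   sum_{j : c in S_j} x_j >= 1  for every compound c,
                           x_j in {0, 1}

Because many optimal selections usually exist, all optima are enumerated by
re-solving with a no-good cut excluding each solution found, and collapsed
into the combined minimum set (their union) — a non-optimal but universal
statement of the cover's composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, sparse

from .scope_extraction import Scope


class InfeasibleCoverError(ValueError):
    """No selection of scopes covers the universe."""


@dataclass
class CoverProblem:
    """Universe of reachable compounds and the scope membership sets."""

    scopes: dict[str, frozenset[str]]
    universe: frozenset[str] = field(init=False)
    #: deterministic solve order: descending member count, then id
    order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.scopes = {
            sid: frozenset(members)
            for sid, members in self.scopes.items()
            if members
        }
        self.universe = frozenset().union(*self.scopes.values()) if self.scopes else frozenset()
        self.order = sorted(self.scopes, key=lambda s: (-len(self.scopes[s]), s))

    @classmethod
    def from_scopes(cls, scopes: Mapping[str, Scope]) -> "CoverProblem":
        return cls({cid: s.member_ids for cid, s in scopes.items()})

    def _milp_parts(self):
        compounds = sorted(self.universe)
        comp_idx = {c: i for i, c in enumerate(compounds)}
        rows, cols = [], []
        for j, sid in enumerate(self.order):
            for c in self.scopes[sid]:
                rows.append(comp_idx[c])
                cols.append(j)
        a = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(compounds), len(self.order)),
        )
        return a


def _solve(problem: CoverProblem, extra_cuts=(), size_cap: int | None = None):
    n = len(problem.order)
    if n == 0:
        if problem.universe:
            raise InfeasibleCoverError("no scopes available to cover the universe")
        return frozenset()
    a = problem._milp_parts()
    constraints = [
        optimize.LinearConstraint(a, lb=1.0, ub=np.inf),
    ]
    for cut in extra_cuts:  # exclude previously found solutions
        row = np.zeros(n)
        for j in cut:
            row[j] = 1.0
        constraints.append(
            optimize.LinearConstraint(row[None, :], lb=-np.inf, ub=len(cut) - 1)
        )
    if size_cap is not None:
        constraints.append(
            optimize.LinearConstraint(np.ones((1, n)), lb=-np.inf, ub=size_cap)
        )
    res = optimize.milp(
        c=np.ones(n),
        integrality=np.ones(n),
        bounds=optimize.Bounds(0, 1),
        constraints=constraints,
    )
    if not res.success:
        return None
    chosen = frozenset(j for j in range(n) if res.x[j] > 0.5)
    return chosen


def solve_min_cover(problem: CoverProblem) -> frozenset[str]:
    """One minimum-cardinality scope selection covering the universe."""
    chosen = _solve(problem)
    if chosen is None:
        raise InfeasibleCoverError("set-cover integer program is infeasible")
    return frozenset(problem.order[j] for j in chosen)


@dataclass
class CoverSolution:
    """All optimal covers, their union, and coverage bookkeeping."""

    optimal_size: int
    solutions: list[frozenset[str]]
    combined: frozenset[str]
    covered_compounds: int
    complete: bool = True
    covered_reactions: int | None = None

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)


def enumerate_optima(problem: CoverProblem, limit: int = 1000) -> CoverSolution:
    """All minimum covers via no-good cuts, collapsed into the combined set.

    Re-solves with each found solution excluded until the objective exceeds
    the optimum or ``limit`` is reached (flagged via ``complete=False``).
    """
    if not problem.scopes:
        return CoverSolution(
            optimal_size=0,
            solutions=[frozenset()],
            combined=frozenset(),
            covered_compounds=0,
        )
    first = _solve(problem)
    if first is None:
        raise InfeasibleCoverError("set-cover integer program is infeasible")
    optimal = len(first)
    found = [first]
    complete = True
    while True:
        if len(found) >= limit:
            if _solve(problem, extra_cuts=found, size_cap=optimal) is not None:
                complete = False
            break
        nxt = _solve(problem, extra_cuts=found, size_cap=optimal)
        if nxt is None:
            break
        found.append(nxt)
    solutions = sorted(
        (frozenset(problem.order[j] for j in sol) for sol in found),
        key=lambda s: sorted(s),
    )
    combined = frozenset().union(*solutions)
    for sol in solutions:
        uncovered = problem.universe - frozenset().union(
            *(problem.scopes[sid] for sid in sol)
        )
        if uncovered:
            raise AssertionError(f"enumerated solution misses {uncovered}")
    return CoverSolution(
        optimal_size=optimal,
        solutions=solutions,
        combined=combined,
        covered_compounds=len(problem.universe),
        complete=complete,
    )


def count_covered_reactions(
    cover: CoverSolution, scopes: Mapping[str, Scope]
) -> int:
    """Distinct reactions on any witness path of any combined-set scope."""
    reactions: set[str] = set()
    for sid in cover.combined:
        for path in scopes[sid].members.values():
            reactions.update(path.reactions)
    cover.covered_reactions = len(reactions)
    return cover.covered_reactions
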