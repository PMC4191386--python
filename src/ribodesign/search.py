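"""Complete constrained inverse folding.

A depth-first branch-and-propagate search over per-position nucleotide
domains.  Constraints: an IUPAC pattern, an optional GC-content window,
compatibility with a set of structures (the sequence must be able to form
every base pair of each), incompatibility with a set of structures (the
sequence must fail at least one pair of each), and — at every leaf — the
requirement that the engine's MFE structure equal the target.

Because every leaf of the constrained space is visited (or pruned only by
sound domain/GC reasoning), an exhausted search certifies that *no*
sequence satisfies the constraints: UNSAT is a proof, not a heuristic
failure.  A node budget turns long runs into resumable partial searches.

Variable ordering: paired positions before unpaired, smaller initial
domains first, ties by position; value ordering: A < C < G < U.  Both are
fixed, so two runs emit byte-identical solution streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

from .engine import ALLOWED_PAIRS, EngineConfig, get_engine
from .iofmt import DotBracket, IupacPattern, RnaSequence

VALUE_ORDER = "ACGU"


class SearchStatus(Enum):
    SOLUTIONS = "solutions"
    UNSAT = "unsat"
    BUDGET_EXHAUSTED = "budget_exhausted"


@dataclass(frozen=True)
class DesignProblem:
    target: DotBracket
    pattern: IupacPattern
    gc_window: tuple[float, float] | None = None
    compatible_with: tuple[DotBracket, ...] = ()
    incompatible_with: tuple[DotBracket, ...] = ()
    max_solutions: int | None = None
    engine: EngineConfig = field(default_factory=lambda: EngineConfig("toy"))

    def __post_init__(self) -> None:
        n = len(self.target)
        if len(self.pattern) != n:
            raise ValueError(
                f"pattern length {len(self.pattern)} != target length {n}"
            )
        for s in (*self.compatible_with, *self.incompatible_with):
            if len(s) != n:
                raise ValueError("constraint structure length differs from target")

    def gc_count_bounds(self) -> tuple[int, int] | None:
        """Translate the percentage window into admissible G+C counts.

        Contiguous decade windows like 30-39% admit any count c with
        lo <= 100 c / n < hi + 1.
        """
        if self.gc_window is None:
            return None
        lo, hi = self.gc_window
        n = len(self.target)
        counts = [c for c in range(n + 1) if lo <= 100.0 * c / n < hi + 1.0]
        if not counts:
            return (1, 0)  # empty window
        return (min(counts), max(counts))


@dataclass
class SearchOutcome:
    status: SearchStatus
    solutions: list[RnaSequence]
    nodes_explored: int
    engine_calls: int = 0
    resume_token: tuple[int, ...] | None = None


UNSAT = None  # sentinel returned by propagate_domains


def _pair_partners(nt: str) -> frozenset[str]:
    return frozenset(b for a, b in ALLOWED_PAIRS if a == nt)


def propagate_domains(problem: DesignProblem) -> list[frozenset[str]] | None:
    """Arc-consistent per-position domains, or None (UNSAT) if any empties.

    For every pair (i, j) of the target and of each compatibility
    structure, a nucleotide survives at i only if some nucleotide in j's
    domain can pair with it (Watson-Crick or GU), and symmetrically.
    """
    domains = [frozenset(d) for d in problem.pattern.domains()]
    arcs = set()
    for s in (problem.target, *problem.compatible_with):
        arcs.update(s.pairs)
    changed = True
    while changed:
        changed = False
        for i, j in arcs:
            di, dj = domains[i - 1], domains[j - 1]
            ni = frozenset(a for a in di if any((a, b) in ALLOWED_PAIRS for b in dj))
            nj = frozenset(b for b in dj if any((a, b) in ALLOWED_PAIRS for a in ni))
            if ni != di or nj != dj:
                domains[i - 1], domains[j - 1] = ni, nj
                changed = True
            if not ni or not nj:
                return UNSAT
    return domains


def _variable_order(problem: DesignProblem, domains: Sequence[frozenset[str]]) -> list[int]:
    paired = set()
    for s in (problem.target, *problem.compatible_with):
        for i, j in s.pairs:
            paired.update((i, j))
    n = len(problem.target)
    return sorted(
        range(1, n + 1),
        key=lambda p: (p not in paired, len(domains[p - 1]), p),
    )


def _satisfies_incompatibilities(seq: str, structures: Sequence[DotBracket]) -> bool:
    for s in structures:
        if all(
            (seq[i - 1], seq[j - 1]) in ALLOWED_PAIRS for i, j in s.pairs
        ):
            return False  # sequence can form ALL pairs -> compatible -> reject
    return True


def enumerate_designs(
    problem: DesignProblem,
    node_budget: int | None = None,
    resume_token: tuple[int, ...] | None = None,
) -> SearchOutcome:
    """Exhaustive DFS over the constrained sequence space.

    Every emitted sequence matches the pattern, lies in the GC window,
    can form all pairs of each compatibility structure, fails at least one
    pair of each incompatibility structure, and has engine MFE structure
    identical to the target.  Duplicates are impossible (each leaf is a
    distinct assignment); emission order is deterministic.
    """
    domains = propagate_domains(problem)
    nodes = 0
    engine_calls = 0
    if domains is UNSAT:
        return SearchOutcome(SearchStatus.UNSAT, [], nodes)

    order = _variable_order(problem, domains)
    n = len(problem.target)
    arcs_by_pos: dict[int, list[int]] = {p: [] for p in range(1, n + 1)}
    for s in (problem.target, *problem.compatible_with):
        for i, j in s.pairs:
            arcs_by_pos[i].append(j)
            arcs_by_pos[j].append(i)
    gc_bounds = problem.gc_count_bounds()
    engine = get_engine(problem.engine)
    target_text = problem.target.text

    solutions: list[RnaSequence] = []
    assignment: dict[int, str] = {}
    # DFS over (depth, value-index) frames; resume skips subtrees left of token
    path: list[int] = []

    def values_at(depth: int, local_domains: Sequence[frozenset[str]]) -> list[str]:
        pos = order[depth]
        return [v for v in VALUE_ORDER if v in local_domains[pos - 1]]

    def gc_feasible(local_domains: Sequence[frozenset[str]]) -> bool:
        if gc_bounds is None:
            return True
        lo, hi = gc_bounds
        mn = sum(1 for d in local_domains if d <= frozenset("GC"))
        mx = sum(1 for d in local_domains if d & frozenset("GC"))
        return mn <= hi and mx >= lo

    def dfs(depth: int, local_domains: list[frozenset[str]]) -> SearchStatus | None:
        nonlocal nodes, engine_calls
        if node_budget is not None and nodes >= node_budget:
            return SearchStatus.BUDGET_EXHAUSTED
        nodes += 1
        if depth == n:
            seq = "".join(assignment[p] for p in range(1, n + 1))
            gc = seq.count("G") + seq.count("C")
            if gc_bounds is not None and not (gc_bounds[0] <= gc <= gc_bounds[1]):
                return None
            if not _satisfies_incompatibilities(seq, problem.incompatible_with):
                return None
            engine_calls += 1
            mfe_struct, _ = engine.mfe(RnaSequence(f"design{len(solutions) + 1}", seq))
            if mfe_struct.text == target_text:
                solutions.append(RnaSequence(f"design{len(solutions)}", seq))
            return None
        if not gc_feasible(local_domains):
            return None
        pos = order[depth]
        start = 0
        if (
            resume_token is not None
            and depth < len(resume_token)
            and list(resume_token[:depth]) == path
        ):
            start = resume_token[depth]
        for vi, value in enumerate(values_at(depth, local_domains)):
            if vi < start:
                continue
            assignment[pos] = value
            path.append(vi)
            child = list(local_domains)
            child[pos - 1] = frozenset(value)
            ok = True
            for q in arcs_by_pos[pos]:
                dq = frozenset(
                    b for b in child[q - 1] if (value, b) in ALLOWED_PAIRS
                )
                child[q - 1] = dq
                if not dq:
                    ok = False
                    break
            if ok:
                res = dfs(depth + 1, child)
                if res is SearchStatus.BUDGET_EXHAUSTED:
                    return res
                if (
                    problem.max_solutions is not None
                    and len(solutions) >= problem.max_solutions
                ):
                    path.pop()
                    del assignment[pos]
                    return SearchStatus.SOLUTIONS
            path.pop()
            del assignment[pos]
        return None

    res = dfs(0, list(domains))
    if res is SearchStatus.BUDGET_EXHAUSTED:
        return SearchOutcome(
            SearchStatus.BUDGET_EXHAUSTED,
            solutions,
            nodes,
            engine_calls,
            resume_token=tuple(path),
        )
    if solutions:
        return SearchOutcome(SearchStatus.SOLUTIONS, solutions, nodes, engine_calls)
    return SearchOutcome(SearchStatus.UNSAT, [], nodes, engine_calls)


def prove_unsat(problem: DesignProblem, node_budget: int | None = None) -> SearchOutcome:
    """Certify unsatisfiability (or refute it with a witness).

    UNSAT is returned only after the whole constrained space has been
    covered; running out of budget yields BUDGET_EXHAUSTED with a resume
    token.  A propagation-level contradiction certifies UNSAT with zero
    engine calls.
    """
    probe = DesignProblem(
        target=problem.target,
        pattern=problem.pattern,
        gc_window=problem.gc_window,
        compatible_with=problem.compatible_with,
        incompatible_with=problem.incompatible_with,
        max_solutions=1,
        engine=problem.engine,
    )
    return enumerate_designs(probe, node_budget=node_budget)
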