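"""Exact DCJ median of three circular genomes.

The median problem asks for a genome M minimising

    ms(A, B, C) = d(A, M) + d(B, M) + d(C, M),

which for circular genomes equals 3n minus the total number of alternating
cycles M forms with A, B and C.  The problem is NP-hard, but small instances
are exactly solvable: brute force enumerates all (2n-1)!! candidate matchings,
and a branch-and-bound search over partial matchings handles moderate n.

The triangle score ts = d(A,B) + d(A,C) + d(B,C) brackets the median score:
ceil(ts/2) <= ms <= floor(2 ts/3), and ms never exceeds the smallest sum of
two pairwise distances (take the shared endpoint as candidate median).  The
branch-and-bound prunes with the ts/2 bound applied to the contracted residual
instance and seeds its incumbent with the best of A, B, C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bpgraph import cycle_count
from .dcj import DcjMove, ScoreTriple, apply_dcj, dcj_distance, triangle_score
from .genome import Genome, GenomeError, all_genomes

__all__ = ["MedianResult", "median_bounds", "median_bruteforce", "median_bnb",
           "median_score", "attains_lower_bound", "ms_delta_under_move",
           "BRUTEFORCE_DEFAULT_CAP"]

BRUTEFORCE_DEFAULT_CAP = 6


@dataclass(frozen=True)
class MedianResult:
    """Outcome of an exact median computation."""

    score: int
    medians: tuple  # tuple[Genome, ...]; all optima (brute force) or first found (B&B)
    distances: tuple  # per median, (d_A, d_B, d_C)
    lower_bound: int
    upper_bound_two_thirds: int
    upper_bound_min_pair: int
    nodes_explored: int
    solver: str

    @property
    def median(self) -> Genome:
        return self.medians[0]


def median_bounds(a: Genome, b: Genome, c: Genome) -> tuple[int, int, int]:
    """(ceil(ts/2), floor(2 ts/3), min pairwise sum) bounds on the median score.

    The lower bound is rounded up because ms is an integer.
    """
    st = triangle_score(a, b, c)
    lower = (st.ts + 1) // 2
    upper_23 = (2 * st.ts) // 3
    upper_minpair = min(st.d_ab + st.d_ac, st.d_ab + st.d_bc, st.d_ac + st.d_bc)
    return lower, upper_23, upper_minpair


def _check_same_n(a: Genome, b: Genome, c: Genome) -> int:
    if not (a.n == b.n == c.n):
        raise GenomeError(f"gene-set mismatch: n = {a.n}, {b.n}, {c.n}")
    return a.n


def median_bruteforce(a: Genome, b: Genome, c: Genome, all_optima: bool = False,
                      max_n: int = BRUTEFORCE_DEFAULT_CAP) -> MedianResult:
    """Exact median by exhaustive enumeration of all perfect matchings.

    Enumerates (2n-1)!! candidates, so n is capped (default 6, i.e. 10,395
    matchings); pass a larger ``max_n`` explicitly to override.  With
    ``all_optima`` every optimal median is returned, sorted canonically.
    """
    n = _check_same_n(a, b, c)
    if n > max_n:
        raise GenomeError(
            f"n={n} exceeds the brute-force cap {max_n} ((2n-1)!! candidates); "
            "use median_bnb or raise max_n explicitly"
        )
    lower, upper_23, upper_minpair = median_bounds(a, b, c)
    best = None
    best_medians: list[Genome] = []
    nodes = 0
    for m in all_genomes(n):
        nodes += 1
        score = sum(dcj_distance(g, m) for g in (a, b, c))
        if best is None or score < best:
            best = score
            best_medians = [m]
        elif all_optima and score == best:
            best_medians.append(m)
    assert best is not None
    medians = tuple(sorted(best_medians, key=lambda g: sorted(g.adjacencies)))
    distances = tuple(
        (dcj_distance(a, m), dcj_distance(b, m), dcj_distance(c, m)) for m in medians
    )
    return MedianResult(best, medians, distances, lower, upper_23, upper_minpair,
                        nodes, "bruteforce")


def _contracted_cycles(end_x: list[int], end_y: list[int], free: list[int],
                       stamp: list[int], tick: int) -> int:
    """Cycle count of the two contracted matchings restricted to free vertices."""
    count = 0
    for start in free:
        if stamp[start] == tick:
            continue
        count += 1
        v = start
        while stamp[v] != tick:
            stamp[v] = tick
            w = end_x[v]
            stamp[w] = tick
            v = end_y[w]
    return count


def median_bnb(a: Genome, b: Genome, c: Genome) -> MedianResult:
    """Exact median by depth-first branch-and-bound over partial matchings.

    The smallest unmatched extremity is paired with each available partner in
    increasing order.  For each input genome the search maintains the
    endpoints of the alternating paths its matching forms with the partial
    median; fixing an edge either extends paths or closes a cycle.  A node is
    pruned when completed cycles plus the residual bound
    (3m + c'_AB + c'_AC + c'_BC) / 2 on the m-gene contracted instance cannot
    beat the incumbent, which starts as the best of A, B, C themselves.
    """
    n = _check_same_n(a, b, c)
    lower, upper_23, upper_minpair = median_bounds(a, b, c)

    # incumbent: best of the three input genomes as candidate median
    seed_scores = [
        (sum(dcj_distance(g, m) for g in (a, b, c)), i)
        for i, m in enumerate((a, b, c))
    ]
    seed_score, seed_idx = min(seed_scores)
    incumbent_score = seed_score
    incumbent = (a, b, c)[seed_idx]

    size = 2 * n + 1
    ends = [g.partner_array() for g in (a, b, c)]  # path-endpoint arrays
    matched = bytearray(size)
    chosen: list[tuple[int, int]] = []
    completed = 0  # cycles closed so far across the three genomes
    nodes = 0
    stamp = [0] * size
    tick = 0

    def free_vertices() -> list[int]:
        return [v for v in range(1, size) if not matched[v]]

    def solve() -> None:
        nonlocal completed, nodes, incumbent_score, incumbent, tick
        if incumbent_score <= lower:
            return
        free = free_vertices()
        m = len(free) // 2
        if m == 0:
            score = 3 * n - completed
            if score < incumbent_score:
                incumbent_score = score
                incumbent = Genome(n, frozenset(chosen))
            return
        # residual bound: future cycles <= (3m + sum of contracted pair cycles)/2
        pair_cycles = 0
        for x, y in ((0, 1), (0, 2), (1, 2)):
            tick += 1
            pair_cycles += _contracted_cycles(ends[x], ends[y], free, stamp, tick)
        max_future = (3 * m + pair_cycles) // 2
        if 3 * n - completed - max_future >= incumbent_score:
            return
        u = free[0]
        for v in free[1:]:
            nodes += 1
            undo: list[tuple[int, int, int, int] | None] = []
            closed = 0
            for e in ends:
                pu, pv = e[u], e[v]
                if pu == v:
                    closed += 1
                    undo.append(None)
                else:
                    e[pu], e[pv] = pv, pu
                    undo.append((pu, pv, u, v))
            matched[u] = matched[v] = 1
            chosen.append((u, v) if u < v else (v, u))
            completed += closed
            solve()
            completed -= closed
            chosen.pop()
            matched[u] = matched[v] = 0
            for e, info in zip(ends, undo):
                if info is not None:
                    pu, pv, uu, vv = info
                    e[pu], e[pv] = uu, vv
            if incumbent_score <= lower:
                return

    solve()
    distances = (
        (dcj_distance(a, incumbent), dcj_distance(b, incumbent), dcj_distance(c, incumbent)),
    )
    return MedianResult(incumbent_score, (incumbent,), distances, lower, upper_23,
                        upper_minpair, nodes, "bnb")


def median_score(a: Genome, b: Genome, c: Genome) -> int:
    """Exact median score, dispatching to brute force for tiny n, else B&B."""
    n = _check_same_n(a, b, c)
    if n <= 4:
        return median_bruteforce(a, b, c).score
    return median_bnb(a, b, c).score


def attains_lower_bound(a: Genome, b: Genome, c: Genome) -> bool:
    """True iff ms(A, B, C) equals ts(A, B, C) / 2 exactly (requires even ts).

    This holds precisely for triples obtainable from a single genome with
    strong DCJs only.
    """
    st = triangle_score(a, b, c)
    if st.ts % 2 != 0:
        return False
    return 2 * median_score(a, b, c) == st.ts


def ms_delta_under_move(a: Genome, b: Genome, c: Genome, move: DcjMove) -> int:
    """Change of the exact median score under one DCJ; always in {-1, 0, +1}."""
    genomes = {"A": a, "B": b, "C": c}
    if move.target not in genomes:
        raise GenomeError(f"move target {move.target!r} not among genome labels A, B, C")
    before = median_score(a, b, c)
    genomes[move.target] = apply_dcj(genomes[move.target], move)
    after = median_score(genomes["A"], genomes["B"], genomes["C"])
    delta = after - before
    assert abs(delta) <= 1, f"median score moved by {delta} under a single DCJ"
    return delta
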