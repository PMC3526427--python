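"""DCJ moves, DCJ distance, triangle score and score deltas.

A DCJ (2-break) replaces two adjacencies of one genome by one of the two
alternative perfect matchings on the same four extremities.  For circular
genomes on n shared genes the DCJ distance is d(A, B) = n - c(A, B), where
c(A, B) counts the alternating cycles of the breakpoint graph; a single move
changes any one pairwise distance by at most 1 and hence the triangle score
ts(A, B, C) = d(A,B) + d(A,C) + d(B,C) by at most 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .bpgraph import cycle_count
from .genome import Adjacency, Genome, GenomeError, adjacency_str, make_adjacency

__all__ = ["DcjMove", "ScoreTriple", "dcj_distance", "triangle_score",
           "apply_dcj", "enumerate_dcjs", "ts_delta", "repairings"]


@dataclass(frozen=True)
class DcjMove:
    """A 2-break: ``removed`` adjacencies replaced by ``added`` on the same 4 extremities.

    ``target`` names the genome the move acts on when the move is used in a
    three-genome context; it may be None for a free-standing move.
    """

    removed: tuple  # (Adjacency, Adjacency)
    added: tuple    # (Adjacency, Adjacency)
    target: str | None = None

    def __post_init__(self) -> None:
        r = set(self.removed[0]) | set(self.removed[1])
        a = set(self.added[0]) | set(self.added[1])
        if len(r) != 4 or r != a:
            raise GenomeError("move must re-pair the same four distinct extremities")
        if set(self.removed) == set(self.added):
            raise GenomeError("move must change the matching")

    def inverse(self) -> "DcjMove":
        return DcjMove(self.added, self.removed, self.target)

    def __str__(self) -> str:
        r = "+".join(adjacency_str(x) for x in self.removed)
        a = "+".join(adjacency_str(x) for x in self.added)
        tgt = f"{self.target}: " if self.target else ""
        return f"{tgt}{r} -> {a}"


@dataclass(frozen=True)
class ScoreTriple:
    """The three pairwise DCJ distances of a genome triple and their sum."""

    d_ab: int
    d_ac: int
    d_bc: int

    @property
    def ts(self) -> int:
        return self.d_ab + self.d_ac + self.d_bc

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.d_ab, self.d_ac, self.d_bc)


def dcj_distance(a: Genome, b: Genome) -> int:
    """Minimal number of DCJs transforming a into b: n - c(a, b)."""
    return a.n - cycle_count(a, b)


def triangle_score(a: Genome, b: Genome, c: Genome) -> ScoreTriple:
    """Pairwise DCJ distances of (a, b, c) and their sum ts."""
    return ScoreTriple(dcj_distance(a, b), dcj_distance(a, c), dcj_distance(b, c))


def repairings(e1: Adjacency, e2: Adjacency) -> tuple[tuple[Adjacency, Adjacency],
                                                      tuple[Adjacency, Adjacency]]:
    """The two alternative matchings on the four extremities of e1, e2.

    Variant 0 pairs the smaller extremity of each edge together ("min-to-min");
    variant 1 is the crossing re-pairing.
    """
    (x, y), (u, v) = e1, e2  # each normalised with first < second
    return ((make_adjacency(x, u), make_adjacency(y, v)),
            (make_adjacency(x, v), make_adjacency(y, u)))


def apply_dcj(g: Genome, move: DcjMove) -> Genome:
    """Apply a 2-break, returning a new genome; the input is unchanged."""
    for adj in move.removed:
        if adj not in g.adjacencies:
            raise GenomeError(f"adjacency {adjacency_str(adj)} not present in genome")
    return Genome(g.n, (g.adjacencies - set(move.removed)) | set(move.added))


def enumerate_dcjs(g: Genome, target: str | None = None) -> Iterator[DcjMove]:
    """All n(n-1) distinct DCJ moves on g, in deterministic order.

    Adjacency pairs are enumerated sorted by (first edge, second edge); for
    each pair the "min-to-min" re-pairing comes first.
    """
    edges = sorted(g.adjacencies)
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            removed = (edges[i], edges[j])
            for added in repairings(edges[i], edges[j]):
                yield DcjMove(removed, added, target)


def ts_delta(a: Genome, b: Genome, c: Genome, move: DcjMove) -> int:
    """Change of ts(a, b, c) under the move; always in {-2, .., +2}.

    Only the two distances involving the target genome are recomputed: the
    third pair's matchings are untouched by the move.
    """
    genomes = {"A": a, "B": b, "C": c}
    if move.target not in genomes:
        raise GenomeError(f"move target {move.target!r} not among genome labels A, B, C")
    moved = apply_dcj(genomes[move.target], move)
    others = [genomes[lbl] for lbl in ("A", "B", "C") if lbl != move.target]
    before = sum(dcj_distance(genomes[move.target], o) for o in others)
    after = sum(dcj_distance(moved, o) for o in others)
    return after - before
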