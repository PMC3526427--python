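"""Breakpoint graphs and alternating-cycle decompositions.

The breakpoint graph of k genomes on the same gene set is the superposition of
their k perfect matchings, one colour per genome, on the shared set of 2n
extremity vertices.  For every pair of colours the union of the two matchings
decomposes into vertex-disjoint cycles whose edges alternate colours; the cycle
count c(A, B) drives the DCJ distance d = n - c(A, B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome import Genome, GenomeError

__all__ = ["BreakpointGraph", "CycleDecomposition", "build_breakpoint_graph",
           "alternating_cycles", "is_identity_bg", "cycle_count", "to_dot"]


@dataclass(frozen=True)
class BreakpointGraph:
    """Superposition of k >= 2 genome matchings on 2n shared extremities."""

    n: int
    colors: tuple  # tuple[str, ...], genome labels in input order
    matchings: dict  # label -> Genome

    def genome(self, color: str) -> Genome:
        try:
            return self.matchings[color]
        except KeyError:
            raise GenomeError(f"unknown color label {color!r}; have {list(self.colors)}") from None


@dataclass(frozen=True)
class CycleDecomposition:
    """Alternating cycles of one colour pair.

    Each cycle is the cyclic vertex sequence of its traversal; ``cycle_id``
    maps every extremity to the index of its cycle.  A length-2 cycle is a
    trivial cycle (the two colours share the adjacency).
    """

    colors: tuple  # (color1, color2)
    cycles: tuple  # tuple[tuple[int, ...], ...]
    cycle_id: dict  # extremity code -> cycle index

    @property
    def count(self) -> int:
        return len(self.cycles)


def build_breakpoint_graph(genomes: Sequence[Genome] | Sequence[tuple[str, Genome]],
                           labels: Sequence[str] | None = None) -> BreakpointGraph:
    """Build the breakpoint graph of two or more genomes on the same gene set.

    Genomes may be given as a plain sequence (labelled A, B, C, ... in order)
    or as (label, genome) pairs.
    """
    if genomes and isinstance(genomes[0], tuple):
        pairs = list(genomes)  # type: ignore[arg-type]
    else:
        if labels is None:
            labels = [chr(ord("A") + i) for i in range(len(genomes))]
        pairs = list(zip(labels, genomes))  # type: ignore[arg-type]
    if len(pairs) < 2:
        raise GenomeError(f"need at least 2 genomes, got {len(pairs)}")
    n = pairs[0][1].n
    for label, g in pairs:
        if g.n != n:
            raise GenomeError(f"genome {label!r} is on 1..{g.n}, expected 1..{n}")
    if len({label for label, _ in pairs}) != len(pairs):
        raise GenomeError("duplicate genome labels")
    return BreakpointGraph(n, tuple(label for label, _ in pairs), dict(pairs))


def alternating_cycles(bg: BreakpointGraph, color1: str, color2: str) -> CycleDecomposition:
    """Decompose the union of two colour matchings into alternating cycles.

    Traversal starts at the smallest unvisited extremity and first follows the
    edge of the lexicographically smaller colour, which fixes a deterministic
    cycle ordering and orientation.
    """
    g1, g2 = bg.genome(color1), bg.genome(color2)
    first, second = (g1, g2) if min(color1, color2) == color1 else (g2, g1)
    p1, p2 = first.partner_array(), second.partner_array()
    cycles: list[tuple[int, ...]] = []
    cycle_id: dict[int, int] = {}
    for start in range(1, 2 * bg.n + 1):
        if start in cycle_id:
            continue
        seq: list[int] = []
        v, use_first = start, True
        while True:
            seq.append(v)
            cycle_id[v] = len(cycles)
            v = p1[v] if use_first else p2[v]
            use_first = not use_first
            if v == start:
                break
        cycles.append(tuple(seq))
    return CycleDecomposition((color1, color2), tuple(cycles), cycle_id)


def cycle_count(a: Genome, b: Genome) -> int:
    """c(A, B): number of alternating cycles in BG(A, B), computed directly."""
    if a.n != b.n:
        raise GenomeError(f"gene-set mismatch: 1..{a.n} vs 1..{b.n}")
    pa, pb = a.partner_array(), b.partner_array()
    seen = bytearray(2 * a.n + 1)
    count = 0
    for start in range(1, 2 * a.n + 1):
        if seen[start]:
            continue
        count += 1
        v = start
        while not seen[v]:
            seen[v] = 1
            w = pa[v]
            seen[w] = 1
            v = pb[w]
    return count


def is_identity_bg(bg: BreakpointGraph) -> bool:
    """True iff all colour matchings coincide (trivial multicycles only)."""
    genomes = list(bg.matchings.values())
    return all(g.adjacencies == genomes[0].adjacencies for g in genomes[1:])


_DOT_COLORS = ("red", "blue", "green", "orange", "purple", "brown")


def to_dot(bg: BreakpointGraph) -> str:
    """GraphViz DOT export of the coloured multigraph, for visual inspection."""
    from .genome import Extremity

    lines = ["graph breakpoint_graph {"]
    for i, label in enumerate(bg.colors):
        color = _DOT_COLORS[i % len(_DOT_COLORS)]
        for u, v in sorted(bg.matchings[label].adjacencies):
            lines.append(
                f'  "{Extremity.from_code(u)}" -- "{Extremity.from_code(v)}"'
                f' [color={color}, label="{label}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
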