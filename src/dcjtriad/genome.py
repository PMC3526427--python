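"""Circular genomes as perfect matchings on gene extremities.

A circular genome over genes ``1..n`` is encoded as a perfect matching on the
``2n`` gene extremities: every gene ``g`` contributes a *tail* and a *head*
vertex, and every adjacency between neighbouring genes on a chromosome becomes
an edge between the corresponding extremities.  Internally extremities are
packed into integers (``tail(g) = 2g - 1``, ``head(g) = 2g``) so that matchings
are plain integer arrays and canonical forms are cheap to compare.

The sign convention is fixed so that a gene traversed in its positive
orientation is entered at its tail and left at its head: for consecutive genes
``x, y`` on a chromosome the adjacency joins ``outgoing(x)`` with
``incoming(y)``, where ``outgoing(+g) = head``, ``outgoing(-g) = tail``,
``incoming(+g) = tail`` and ``incoming(-g) = head``.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple, Sequence, TextIO

__all__ = [
    "End",
    "Extremity",
    "Adjacency",
    "Genome",
    "Chromosome",
    "GenomeError",
    "ParseError",
    "tail",
    "head",
    "parse_genome",
    "decode_chromosomes",
    "genome_to_string",
    "read_grimm",
    "write_grimm",
    "random_genome",
    "identity_genome",
    "all_genomes",
]


class GenomeError(ValueError):
    """Invalid genome structure or mismatched gene sets."""


class ParseError(GenomeError):
    """Malformed cycle-notation or GRIMM input."""


class End(Enum):
    TAIL = "t"
    HEAD = "h"


def tail(gene: int) -> int:
    """Integer code of gene's tail extremity."""
    return 2 * gene - 1


def head(gene: int) -> int:
    """Integer code of gene's head extremity."""
    return 2 * gene


class Extremity(NamedTuple):
    """One of the two ends of a gene."""

    gene: int
    end: End

    @property
    def code(self) -> int:
        return tail(self.gene) if self.end is End.TAIL else head(self.gene)

    @classmethod
    def from_code(cls, code: int) -> "Extremity":
        gene, rem = divmod(code + 1, 2)
        return cls(gene, End.TAIL if rem == 0 else End.HEAD)

    def __str__(self) -> str:
        return f"{self.gene}{self.end.value}"


# An adjacency is an unordered pair of extremity codes, normalised (u, v), u < v.
Adjacency = tuple[int, int]


def make_adjacency(u: int, v: int) -> Adjacency:
    if u == v:
        raise GenomeError(f"adjacency must join two distinct extremities, got {u!r} twice")
    return (u, v) if u < v else (v, u)


def adjacency_str(adj: Adjacency) -> str:
    return "{%s,%s}" % (Extremity.from_code(adj[0]), Extremity.from_code(adj[1]))


@dataclass(frozen=True)
class Genome:
    """A circular genome: a perfect matching on the 2n extremities.

    ``adjacencies`` is a frozenset of normalised extremity-code pairs.  Two
    genomes are equal iff they have the same ``n`` and the same matching, which
    makes equality rotation- and reflection-invariant by construction.
    """

    n: int
    adjacencies: frozenset  # frozenset[Adjacency]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GenomeError(f"gene count must be >= 1, got {self.n}")
        seen: set[int] = set()
        for adj in self.adjacencies:
            u, v = adj
            for x in (u, v):
                if not 1 <= x <= 2 * self.n:
                    raise GenomeError(f"extremity code {x} out of range for n={self.n}")
                if x in seen:
                    raise GenomeError(
                        f"extremity {Extremity.from_code(x)} occurs in more than one adjacency"
                    )
                seen.add(x)
        if len(self.adjacencies) != self.n:
            raise GenomeError(
                f"expected {self.n} adjacencies for a perfect matching, got {len(self.adjacencies)}"
            )

    def partner_array(self) -> list[int]:
        """partner[x] = extremity matched with x; index 0 unused."""
        partner = [0] * (2 * self.n + 1)
        for u, v in self.adjacencies:
            partner[u] = v
            partner[v] = u
        return partner

    def has_adjacency(self, adj: Adjacency) -> bool:
        return adj in self.adjacencies

    def __str__(self) -> str:
        return genome_to_string(self)

    def __repr__(self) -> str:
        return f"Genome({genome_to_string(self)!r}, n={self.n})"


@dataclass(frozen=True)
class Chromosome:
    """Presentation form of one circular chromosome: a canonical signed gene order.

    Canonical form starts at the smallest gene id of the cycle, oriented so that
    gene carries a positive sign; the adjacency set is invariant under rotation
    and reflection, so equal chromosomes canonicalise identically.
    """

    order: tuple  # tuple[int, ...], signed gene ids

    def __str__(self) -> str:
        return "(" + ", ".join(str(g) for g in self.order) + ")"


def _genome_from_chromosome_lists(chroms: Sequence[Sequence[int]], n: int | None) -> Genome:
    genes_seen: set[int] = set()
    max_gene = 0
    for chrom in chroms:
        if not chrom:
            raise ParseError("empty chromosome '()'")
        for g in chrom:
            a = abs(g)
            if a == 0:
                raise ParseError(f"gene id 0 is not allowed (token {g!r})")
            if a in genes_seen:
                raise ParseError(f"duplicate gene {a}")
            genes_seen.add(a)
            max_gene = max(max_gene, a)
    if n is None:
        n = max_gene
    if max_gene > n:
        raise ParseError(f"gene {max_gene} out of range for n={n}")
    missing = set(range(1, n + 1)) - genes_seen
    if missing:
        raise ParseError(f"missing genes: {sorted(missing)}")

    adjacencies: set[Adjacency] = set()
    for chrom in chroms:
        for x, y in zip(chrom, chrom[1:] + [chrom[0]]):
            out = head(x) if x > 0 else tail(-x)
            inc = tail(y) if y > 0 else head(-y)
            adjacencies.add(make_adjacency(out, inc))
    return Genome(n, frozenset(adjacencies))


_CHROM_RE = re.compile(r"\(([^()]*)\)")


def parse_genome(text: str, n: int | None = None) -> Genome:
    """Parse parenthesised signed-cycle notation, e.g. ``"(1, -6, -7)(2, 5, 4, 3)"``.

    Each parenthesised group is one circular chromosome; every gene ``1..n``
    must appear exactly once (``n`` defaults to the largest absolute gene id).
    """
    stripped = re.sub(r"[\s,]", "", re.sub(_CHROM_RE, "", text))
    if stripped:
        raise ParseError(f"unexpected token outside parentheses: {stripped!r}")
    groups = _CHROM_RE.findall(text)
    if not groups:
        raise ParseError(f"no parenthesised chromosome found in {text!r}")
    chroms: list[list[int]] = []
    for group in groups:
        tokens = [t for t in re.split(r"[,\s]+", group.strip()) if t]
        if not tokens:
            raise ParseError("empty chromosome '()'")
        try:
            chroms.append([int(t) for t in tokens])
        except ValueError as exc:
            raise ParseError(f"invalid gene token in {group!r}: {exc}") from None
    return _genome_from_chromosome_lists(chroms, n)


def decode_chromosomes(g: Genome) -> tuple[Chromosome, ...]:
    """Decode the matching into canonical circular chromosomes.

    Traversal alternates the implicit gene edges (tail-head of each gene) with
    the genome's adjacencies; the matching invariant guarantees only cycles.
    Chromosomes are returned sorted by their smallest gene id.
    """
    partner = g.partner_array()
    unvisited = set(range(1, g.n + 1))
    chromosomes: list[Chromosome] = []
    while unvisited:
        start = min(unvisited)
        order: list[int] = []
        gene, sign = start, 1
        while True:
            order.append(sign * gene)
            unvisited.discard(gene)
            out = head(gene) if sign > 0 else tail(gene)
            nxt = partner[out]
            gene, rem = divmod(nxt + 1, 2)
            sign = 1 if rem == 0 else -1  # entered at tail -> positive
            if gene == start:
                break
        chromosomes.append(Chromosome(tuple(order)))
    return tuple(sorted(chromosomes, key=lambda c: abs(c.order[0])))


def genome_to_string(g: Genome) -> str:
    return "".join(str(c) for c in decode_chromosomes(g))


def identity_genome(n: int) -> Genome:
    """The genome ``(1)(2)...(n)``: every gene its own circular chromosome."""
    return Genome(n, frozenset(make_adjacency(tail(g), head(g)) for g in range(1, n + 1)))


def read_grimm(stream: TextIO | Iterable[str]) -> list[tuple[str, Genome]]:
    """Read a multi-genome GRIMM file (circular dialect, ``@`` terminators).

    Linear chromosomes (``$`` terminator) are rejected; all genomes must share
    the gene set ``1..n``.
    """
    genomes: list[tuple[str, Genome]] = []
    name: str | None = None
    chroms: list[list[int]] = []

    def flush() -> None:
        nonlocal name, chroms
        if name is not None:
            if not chroms:
                raise ParseError(f"genome {name!r} has no chromosomes")
            genomes.append((name, _genome_from_chromosome_lists(chroms, None)))
        name, chroms = None, []

    for lineno, raw in enumerate(stream, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise ParseError(f"line {lineno}: empty genome name")
            continue
        if name is None:
            raise ParseError(f"line {lineno}: chromosome data before any '>' header")
        if "$" in line:
            raise ParseError(
                f"line {lineno}: linear chromosome terminator '$' is not supported "
                "(only circular chromosomes, terminated by '@')"
            )
        for part in line.split("@"):
            tokens = part.split()
            if tokens:
                try:
                    chroms.append([int(t) for t in tokens])
                except ValueError:
                    raise ParseError(f"line {lineno}: invalid gene token in {part!r}") from None
        if not line.endswith("@"):
            raise ParseError(f"line {lineno}: chromosome line must end with '@'")
    flush()

    if genomes:
        n0 = genomes[0][1].n
        for gname, g in genomes[1:]:
            if g.n != n0:
                raise GenomeError(
                    f"genome {gname!r} has gene set 1..{g.n}, expected 1..{n0}"
                )
    return genomes


def write_grimm(genomes: Sequence[tuple[str, Genome]], stream: TextIO) -> None:
    """Write genomes in the circular GRIMM dialect; round-trips with read_grimm."""
    for name, g in genomes:
        stream.write(f">{name}\n")
        for chrom in decode_chromosomes(g):
            stream.write(" ".join(str(x) for x in chrom.order) + " @\n")


def random_genome(n: int, seed: int | random.Random) -> Genome:
    """Uniform random perfect matching on the 2n extremities.

    A seeded shuffle of all extremities paired sequentially; every matching
    (there are (2n-1)!! of them) is equally likely.
    """
    if n < 1:
        raise GenomeError(f"gene count must be >= 1, got {n}")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    codes = list(range(1, 2 * n + 1))
    rng.shuffle(codes)
    adjacencies = frozenset(
        make_adjacency(codes[2 * i], codes[2 * i + 1]) for i in range(n)
    )
    return Genome(n, adjacencies)


def all_genomes(n: int) -> Iterator[Genome]:
    """Enumerate all (2n-1)!! perfect matchings on 2n extremities.

    Intended for exhaustive checks at small n; the count grows as 1, 3, 15,
    105, 945, 10395 for n = 1..6.
    """
    codes = list(range(1, 2 * n + 1))

    def rec(avail: list[int], acc: list[Adjacency]) -> Iterator[Genome]:
        if not avail:
            yield Genome(n, frozenset(acc))
            return
        u = avail[0]
        for i in range(1, len(avail)):
            v = avail[i]
            rest = avail[1:i] + avail[i + 1 :]
            acc.append((u, v))
            yield from rec(rest, acc)
            acc.pop()

    yield from rec(codes, [])
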