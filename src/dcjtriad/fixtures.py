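"""Worked examples and generators for property-test inputs.

The three small genome triples exercised throughout the package — the 2-gene
triple whose breakpoint graph has one alternating cycle per colour pair, the
4-gene triple admitting no triangle-score-decreasing DCJ, and the 11-gene
counterexample where a strong fusion leaves the median score unchanged — are
reproduced here programmatically together with their expected scores, plus a
scalable family whose median-score gap grows linearly and seeded random-triple
generators.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .dcj import DcjMove
from .genome import Genome, GenomeError, identity_genome, parse_genome, random_genome
from .strong import MoveRecord, find_strong_pair, apply_strong_dcj

__all__ = ["PaperExample", "figure1", "figure3", "figure4", "theorem7_family",
           "random_triple"]

_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class PaperExample:
    """A worked example: labelled genomes plus their expected quantities."""

    label: str
    genomes: dict  # label -> Genome
    expected: dict  # quantity name -> value

    def triple(self) -> tuple[Genome, Genome, Genome]:
        return self.genomes["A"], self.genomes["B"], self.genomes["C"]


def figure1() -> PaperExample:
    """Two genes: A = (1)(2), B = (1, 2), C = (1, -2).

    The smallest triple where all three pairwise distances equal the maximum
    n - 1 = 1; every colour pair forms a single alternating cycle.
    """
    return PaperExample(
        "figure1",
        {"A": parse_genome("(1)(2)"), "B": parse_genome("(1, 2)"),
         "C": parse_genome("(1, -2)")},
        {"distances": (1, 1, 1), "ts": 3, "ms": 2, "ab_cycles": 1},
    )


def figure3() -> PaperExample:
    """Four genes: A = (1)(2)(3)(4), B = (1, 2)(3, 4), C = (1, -2)(3, -4).

    No DCJ on any of the three genomes can lower the triangle score by 2, and
    the median score exceeds the ts/2 lower bound by 1.
    """
    return PaperExample(
        "figure3",
        {"A": parse_genome("(1)(2)(3)(4)"), "B": parse_genome("(1, 2)(3, 4)"),
         "C": parse_genome("(1, -2)(3, -4)")},
        {"distances": (2, 2, 2), "ts": 6, "ms": 4, "ms_minus_half_ts": 1,
         "ts_decreasing_dcj_exists": False},
    )


def figure4() -> PaperExample:
    """Eleven genes: the strong-fusion counterexample.

    B' is obtained from B by a single fusion of its two chromosomes; the move
    is strong (ts rises from 24 to 26) yet the median score stays 15.  M and
    M' are median genomes of the original and fused triples respectively.
    """
    genomes = {
        "A": parse_genome("(1, -6, -7, -8, -9, -10, -11)(2, 5, 4, 3)"),
        "B": parse_genome("(1, 8, 9, 10, 11)(2, 3, 4, 5, 6, 7)"),
        "C": parse_genome("(1, -3, 4, 10, -8, 11, 9, 5, -7, 6, 2)"),
        "B'": parse_genome("(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)"),
        "M": parse_genome("(1, -6, -5, -2, -3, -4, -7, -10, -11, 8, 9)"),
        "M'": parse_genome("(1, -3, -4, -5, -2, -6, 7, -10, -11, 8, 9)"),
    }
    return PaperExample(
        "figure4",
        genomes,
        {
            "distances": (8, 8, 8), "ts": 24, "ms": 15,
            "d_AM": 3, "d_BM": 5, "d_CM": 7,
            "distances_fused": (9, 8, 9), "ts_fused": 26, "ms_fused": 15,
            "d_AM'": 4, "d_B'M'": 6, "d_CM'": 5,
        },
    )


def theorem7_family(n: int) -> tuple[Genome, Genome, Genome]:
    """Genome triple on 4n genes whose median score exceeds ts/2 by exactly n.

    n disjoint copies of the 4-gene block A = (1)(2)(3)(4), B = (1, 2)(3, 4),
    C = (1, -2)(3, -4), copy i shifted to genes 4i+1..4i+4.  Each block
    contributes 6 to the triangle score and 4 to the median score.
    """
    if n < 1:
        raise GenomeError(f"need n >= 1 copies, got {n}")
    a_parts, b_parts, c_parts = [], [], []
    for i in range(n):
        g = [4 * i + k for k in (1, 2, 3, 4)]
        a_parts.append(f"({g[0]})({g[1]})({g[2]})({g[3]})")
        b_parts.append(f"({g[0]}, {g[1]})({g[2]}, {g[3]})")
        c_parts.append(f"({g[0]}, -{g[1]})({g[2]}, -{g[3]})")
    return (parse_genome("".join(a_parts)), parse_genome("".join(b_parts)),
            parse_genome("".join(c_parts)))


def random_triple(n: int, mode: str = "uniform", seed: int = 0, k: int = 0
                  ) -> tuple[Genome, Genome, Genome]:
    """Seeded random genome triples for property tests.

    ``uniform``: three independent uniform random matchings.  ``strong-walk``:
    the identity triple evolved by k strong DCJs applied round-robin to A, B,
    C — such triples always attain the ts/2 median lower bound.
    """
    if mode == "uniform":
        rng = random.Random(seed)
        return tuple(random_genome(n, rng) for _ in range(3))  # type: ignore[return-value]
    if mode != "strong-walk":
        raise GenomeError(f"unknown mode {mode!r}; expected 'uniform' or 'strong-walk'")
    if k < 0:
        raise GenomeError(f"need k >= 0 strong moves, got {k}")
    ident = identity_genome(n)
    genomes = {"A": ident, "B": ident, "C": ident}
    for i in range(k):
        mover = _LABELS[i % 3]
        pair = find_strong_pair(mover, genomes["A"], genomes["B"], genomes["C"])
        if pair is None:
            raise GenomeError(
                f"strong walk infeasible: no strong pair for {mover} after {i} of {k} moves"
            )
        moved, _ = apply_strong_dcj(mover, genomes["A"], genomes["B"], genomes["C"], pair)
        genomes[mover] = moved
    return genomes["A"], genomes["B"], genomes["C"]
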