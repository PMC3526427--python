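# Methods

## Genome model

A circular genome over genes `1..n` is a perfect matching on the `2n` gene
extremities. Gene `g` contributes a tail and a head, packed as integers
`tail(g) = 2g - 1`, `head(g) = 2g`; an adjacency is an unordered pair of
extremity codes. The matching plus the implicit gene edges (tail-head of each
gene) decomposes into cycles, one per circular chromosome, so the matching
invariant alone guarantees a valid circular genome. Linear chromosomes,
unequal gene content, duplicated genes and indels are out of scope.

The sign convention is pinned once: traversing gene `g` positively enters at
its tail and leaves at its head, so consecutive genes `x, y` contribute the
adjacency `{outgoing(x), incoming(y)}` with `outgoing(+g) = head`,
`outgoing(-g) = tail`, `incoming(+g) = tail`, `incoming(-g) = head`. Any
self-consistent convention yields identical distances; pinning one makes
adjacency sets and fixtures byte-for-byte comparable. Canonical chromosome
strings start at the smallest gene id of the cycle, oriented to give that
gene a positive sign, with chromosomes listed by smallest gene — equality of
genomes is equality of matchings, hence rotation- and reflection-invariant.

## Distances, cycles and moves

The breakpoint graph of k genomes is the superposition of their matchings on
the shared vertex set. For each colour pair the union of the two matchings
splits into vertex-disjoint alternating cycles; cycle traversal starts at the
smallest unvisited extremity and follows the lexicographically smaller colour
first, which fixes deterministic cycle ids (used for tie-breaking below).
The DCJ distance is `d(A, B) = n - c(A, B)`. A DCJ (2-break) replaces two
adjacencies of one genome by one of the two alternative pairings of the same
four extremities; enumeration orders adjacency pairs lexicographically and
lists the "min-to-min" re-pairing first, giving the `n(n-1)` moves a stable
order for property tests. Triangle-score deltas recompute only the two
distances involving the moved genome, since the third pair's matchings are
untouched.

## Strong moves and prescribed-distance construction

A strong DCJ raises ts by 2. The finder partitions the moving genome's edges
by their (cycle id vs first other genome, cycle id vs second other genome)
coordinates and returns the lexicographically first edge pair differing in
both coordinates; such a pair exists exactly when both of the mover's
distances are below `n - 1` (with a single cycle in either decomposition no
pair can differ there, and the pigeonhole argument on the two partitions
guarantees a pair otherwise). Any 2-break on the pair merges two cycles in
each decomposition, so the min-to-min re-pairing is used and the +2 delta is
asserted at run time.

`construct_triple` realises a distance triple `(p, q, r)` (each in
`[0, n-1]`, triangle inequality) exactly. Targets are sorted ascending,
built, and the three output genomes permuted back to the caller's order. For
an even sum the identity triple absorbs `(p+q-r)/2` strong moves into A,
`(p+r-q)/2` into B and `(q+r-p)/2` into C, phase by phase; each strong move
adds 1 to both of its mover's distances, so the final distances are exact and
the phase ordering keeps the existence precondition satisfied throughout
(before every move the mover's distances are at most their target minus 1,
hence at most `n - 2`). For an odd sum the smallest target is necessarily
positive, and the construction first reaches distances (1, 1, 1) on genes 1
and 2 — a strong move in B creating the chromosome `(1, 2)` followed by a
non-strong move in C creating `(1, -2)`, a sequence verified by direct
computation — then proceeds as in the even case on `(p-1, q-1, r-1)`. Total
strong moves: `floor((p+q+r)/2)`. A `seed` parameter is accepted for
interface stability but unused: pair selection is deterministically
tie-broken. Runtime assertions re-check the precondition before every strong
move, making the constructive argument executable.

## Exact median solvers

Brute force enumerates all `(2n-1)!!` matchings and is capped at `n = 6`
(10,395 candidates) unless the caller raises the cap explicitly; with
`all_optima` it returns every optimal median in canonical order.

The branch-and-bound searches partial matchings depth-first, always pairing
the smallest unmatched extremity with each available partner in increasing
order (deterministic node counts; the first optimal found is reported). For
each input genome the solver maintains the endpoints of the alternating
paths formed by that genome's matching and the partial median: fixing a
median edge either splices two paths or closes a cycle. Since the median's
total distance is `3n` minus the total number of cycles it closes, the
search maximises cycles. Pruning uses the observation that the path-endpoint
maps restricted to unmatched extremities are themselves perfect matchings on
the `2m` remaining extremities — the contracted residual instance — and the
`ts/2` lower bound applied there caps the future cycle count at
`(3m + c'_AB + c'_AC + c'_BC) / 2`, where `c'` are the contracted pairwise
cycle counts recomputed in O(m) per node. The incumbent is seeded with the
best of A, B, C themselves (the min-pairwise-sum upper bound), and the
search stops early once the incumbent meets the global lower bound
`ceil(ts/2)`. No adequate-subgraph preprocessing is used; the bound alone
decomposes block-structured instances well in practice (the 8-gene
two-block instance solves in a few hundred nodes, the 11-gene
counterexample in ~1,500).

Bounds are reported as integers: the lower bound as `ceil(ts/2)` (the median
score is integral), the uppers as `floor(2 ts/3)` and the smallest pairwise
sum. `attains_lower_bound` requires an even ts and an exact solve;
`ms_delta_under_move` solves both states exactly and asserts the result lies
in `{-1, 0, +1}`.

## Random generators and what they do (not) show

`random_genome` draws a uniform matching (seeded shuffle of the extremities,
paired sequentially), so every one of the `(2n-1)!!` genomes is equally
likely — verified by a chi-square test at `n = 2`. `random_triple` offers
two modes: `uniform` (three independent draws) and `strong-walk` (the
identity triple evolved by k strong moves, round-robin over A, B, C), whose
outputs attain `ms = ts/2` by construction. These generators exercise the
combinatorial claims — the theorems hold for *all* genomes, so uniform
sampling is the appropriate stress test — but uniform random matchings are
not evolutionary models: real genomes have few chromosomes and correlated
rearrangement histories. Passing tests certify the combinatorics, not any
biological realism. Property tests run at `n <= 7` for distance axioms and
strong-move existence and `n <= 5` for exact-median properties; these sizes
already give non-trivial cycle structure while keeping the exhaustive
oracles (all matchings, all moves, all feasible distance triples) cheap.

## Known limitations

- The branch-and-bound has no performance guarantee: the median problem is
  NP-hard, and instances much beyond ~15 genes, or with triangle scores far
  from their lower bound, may explode. It is exact wherever it terminates.
- Only one median is returned by the branch-and-bound; use the brute-force
  solver with `all_optima` (small n) to enumerate ties.
- Whether the `2 ts/3` upper bound is tight is an open question; the package
  reports the bound but never assumes tightness.
- Gene identifiers are positive integers `1..n`; mapping string gene names
  to ids is left to the caller.
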