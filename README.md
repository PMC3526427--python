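# dcjtriad

Pairwise DCJ distances, triangle score, strong rearrangements and exact
medians of three circular genomes.

## The problem

Comparative genomics measures the evolutionary remoteness of two genomes by
their *rearrangement distance*: the minimal number of large-scale events
(reversals, translocations, fusions, fissions) turning one into the other.
Under the Double-Cut-and-Join (DCJ, or 2-break) model this distance is
computable in linear time, but its natural three-genome generalisation — the
*median score*

    ms(A, B, C) = min over genomes M of  d(A, M) + d(B, M) + d(C, M)

— is NP-hard, which makes cheap surrogates attractive. The cheapest is the
*triangle score* ts(A, B, C) = d(A,B) + d(A,C) + d(B,C), which brackets the
median score:

    ts / 2  <=  ms  <=  2 ts / 3,      and also   ms <= min pairwise sum.

`dcjtriad` is a toolkit for studying exactly this interplay on circular
genomes. It provides:

- **genome model and I/O** — circular genomes over genes `1..n` as perfect
  matchings on the `2n` gene extremities (tails and heads), parsed from
  signed-cycle notation like `(1, -6, -7)(2, 5, 4, 3)` or from GRIMM files
  (circular dialect, `@` terminators);
- **breakpoint graphs** — the superposition of the genome matchings, one
  colour each, with alternating-cycle decomposition per colour pair; the
  distance is `d(A, B) = n - c(A, B)` with `c` the cycle count;
- **DCJ moves** — application, exhaustive enumeration (`n(n-1)` moves), and
  triangle-score deltas (always in `-2..+2`);
- **strong DCJs** — moves that raise ts by 2 (pushing one genome one step
  away from both others). Whenever both of a genome's distances to the other
  two are below the maximum `n - 1`, a strong move on it exists and is found
  constructively; on top of this the package builds genome triples with any
  prescribed pairwise distances `(p, q, r)` satisfying the triangle
  inequality, using `floor((p+q+r)/2)` strong moves;
- **exact medians** — brute force over all `(2n-1)!!` matchings for tiny `n`,
  and a branch-and-bound over partial matchings (pruned with the `ts/2`
  bound on the contracted residual instance) for moderate `n`. The solvers
  expose the bounds, all optimal medians (brute force) and search statistics.

The headline scientific fact the package reproduces: a strong move raises the
median-score *lower bound* by 1, yet need not raise the median score itself —
on an 11-gene triple with distances (8, 8, 8) a strong fusion lifts ts from
24 to 26 while ms stays 15. The gap `ms - ts/2` is likewise unbounded: a
family of 4n-gene triples achieves gap exactly n.

## Worked example

The 11-gene counterexample triple:

```
$ dcjtriad triangle "(1, -6, -7, -8, -9, -10, -11)(2, 5, 4, 3)" \
                    "(1, 8, 9, 10, 11)(2, 3, 4, 5, 6, 7)" \
                    "(1, -3, 4, 10, -8, 11, 9, 5, -7, 6, 2)"
d(A,B)=8 d(A,C)=8 d(B,C)=8 ts=24
```

All three pairwise distances are 8, so the triangle score is 24 and the
median score must lie in `[ceil(24/2), min(floor(2*24/3), 8+8)] = [12, 16]`.
The exact solver settles it:

```
$ dcjtriad median "(1, -6, -7, -8, -9, -10, -11)(2, 5, 4, 3)" \
                  "(1, 8, 9, 10, 11)(2, 3, 4, 5, 6, 7)" \
                  "(1, -3, 4, 10, -8, 11, 9, 5, -7, 6, 2)"
ms=15 bounds=[12, 16] nodes=1517
median (1)(2, 3, 4, 5)(6, 7)(8, 9, 10, 11)  distances (6, 2, 7)
```

The optimum is 15 (three above the lower bound), found after exploring 1517
branch-and-bound nodes; the reported median genome sits at distances
6 + 2 + 7 = 15 from the three inputs. Medians are generally not unique — the
4-gene triple below has nine of them:

```
$ dcjtriad median "(1)(2)(3)(4)" "(1,2)(3,4)" "(1,-2)(3,-4)" --solver brute --all-optima
ms=4 bounds=[3, 4] nodes=105
median (1)(2)(3)(4)  distances (0, 2, 2)
median (1)(2)(3, -4)  distances (1, 2, 1)
...
```

Here ts = 6, so ms = 4 exceeds the lower bound 3: this triple cannot be
produced from a single genome by strong moves alone, and indeed no DCJ
decreases its triangle score by 2.

Triples with prescribed distances are built constructively:

```
$ dcjtriad construct --p 2 --q 3 --r 3 --n 5 --out triple.grimm
wrote triple.grimm with distances (2, 3, 3) (4 strong moves, log in triple.grimm.moves.txt)
```

`dcjtriad verify-paper` recomputes every worked-example quantity and prints a
pass/fail table; `dcjtriad fixtures --figure 4 --out DIR` exports the
examples as GRIMM + expected-value JSON.

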