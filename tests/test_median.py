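"""Exact median: bounds, brute force vs branch-and-bound, score dynamics."""

import random

import pytest

from dcjtriad.dcj import apply_dcj, dcj_distance, enumerate_dcjs, triangle_score, ts_delta
from dcjtriad.genome import GenomeError, identity_genome, parse_genome, random_genome
from dcjtriad.median import (
    attains_lower_bound,
    median_bnb,
    median_bounds,
    median_bruteforce,
    median_score,
    ms_delta_under_move,
)
from dcjtriad.fixtures import random_triple, theorem7_family
from dcjtriad.strong import find_strong_pair, apply_strong_dcj


class TestBounds:
    def test_eleven_gene_example(self, fig4):
        assert median_bounds(*fig4.triple()) == (12, 16, 16)

    def test_identical_triple(self):
        g = random_genome(4, 2)
        assert median_bounds(g, g, g) == (0, 0, 0)

    def test_four_gene_example(self, fig3):
        lower, upper_23, upper_minpair = median_bounds(*fig3.triple())
        assert (lower, upper_23, upper_minpair) == (3, 4, 4)

    @pytest.mark.parametrize("seed", range(50))
    def test_ordering_on_random_triples(self, seed):
        rng = random.Random(seed)
        a, b, c = random_triple(rng.randint(2, 7), "uniform", seed)
        lower, upper_23, upper_minpair = median_bounds(a, b, c)
        assert lower <= upper_23 and lower <= upper_minpair


class TestBruteForce:
    def test_four_gene_example_score(self, fig3):
        result = median_bruteforce(*fig3.triple())
        assert result.score == 4
        assert result.nodes_explored == 105  # (2*4-1)!!

    def test_identical_triple_has_unique_median(self):
        g = random_genome(3, 17)
        result = median_bruteforce(g, g, g, all_optima=True)
        assert result.score == 0 and result.medians == (g,)

    def test_two_gene_example_score(self, fig1):
        # one of the inputs is optimal: d to the two others is 1 + 1, and the
        # lower bound ceil(3/2) = 2 forces ms = 2
        result = median_bruteforce(*fig1.triple(), all_optima=True)
        assert result.score == 2
        assert fig1.genomes["A"] in result.medians

    def test_score_matches_distance_sum(self, fig3):
        result = median_bruteforce(*fig3.triple())
        a, b, c = fig3.triple()
        m = result.median
        assert result.score == sum(dcj_distance(g, m) for g in (a, b, c))
        assert result.distances[0] == tuple(dcj_distance(g, m) for g in (a, b, c))

    def test_cap_refuses_large_n(self):
        g = identity_genome(7)
        with pytest.raises(GenomeError, match="median_bnb"):
            median_bruteforce(g, g, g)


class TestBranchAndBound:
    def test_eleven_gene_example(self, fig4):
        result = median_bnb(*fig4.triple())
        assert result.score == 15
        m = result.median
        assert sum(result.distances[0]) == 15
        a, b, c = fig4.triple()
        assert sum(dcj_distance(g, m) for g in (a, b, c)) == 15

    def test_eleven_gene_fused_example(self, fig4):
        a, _, c = fig4.triple()
        assert median_bnb(a, fig4.genomes["B'"], c).score == 15

    def test_printed_medians_attain_the_optimum(self, fig4):
        a, b, c = fig4.triple()
        m, mp, bp = (fig4.genomes[k] for k in ("M", "M'", "B'"))
        assert sum(dcj_distance(g, m) for g in (a, b, c)) == 15
        assert sum(dcj_distance(g, mp) for g in (a, bp, c)) == 15

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_brute_force(self, seed):
        n = 2 + seed % 4
        a, b, c = random_triple(n, "uniform", seed)
        assert median_bnb(a, b, c).score == median_bruteforce(a, b, c).score

    @pytest.mark.parametrize("seed", range(100))
    def test_triangle_score_bounds_hold(self, seed):
        n = 2 + seed % 4
        a, b, c = random_triple(n, "uniform", 10_000 + seed)
        ts = triangle_score(a, b, c).ts
        ms = median_bnb(a, b, c).score
        lower, upper_23, upper_minpair = median_bounds(a, b, c)
        assert lower <= ms <= upper_23
        assert ms <= upper_minpair
        assert 2 * ms >= ts and 3 * ms <= 2 * ts


class TestTheorem7Family:
    @pytest.mark.parametrize("n, solver", [(1, median_bruteforce), (2, median_bnb)])
    def test_gap_grows_linearly(self, n, solver):
        a, b, c = theorem7_family(n)
        ts = triangle_score(a, b, c).ts
        assert ts == 6 * n
        assert solver(a, b, c).score - ts // 2 == n


class TestAttainsLowerBound:
    def test_strong_walk_triples_attain(self):
        for seed in range(5):
            a, b, c = random_triple(4, "strong-walk", seed=seed, k=3)
            assert triangle_score(a, b, c).ts == 6
            assert attains_lower_bound(a, b, c)

    def test_four_gene_example_does_not(self, fig3):
        assert not attains_lower_bound(*fig3.triple())

    def test_identical_triple_attains(self):
        g = random_genome(3, 23)
        assert attains_lower_bound(g, g, g)

    def test_attaining_triples_unwind_by_ts_decreasing_moves(self):
        # reverse direction: ms = ts/2 implies the triple unwinds to a single
        # genome with ts-decreasing-by-2 moves in exactly ms steps

        def unwind(genomes, steps_left):
            if genomes["A"] == genomes["B"] == genomes["C"]:
                return steps_left == 0
            if steps_left == 0:
                return False
            for lbl in "ABC":
                for move in enumerate_dcjs(genomes[lbl], lbl):
                    if ts_delta(genomes["A"], genomes["B"], genomes["C"], move) == -2:
                        nxt = dict(genomes)
                        nxt[lbl] = apply_dcj(genomes[lbl], move)
                        if unwind(nxt, steps_left - 1):
                            return True
            return False

        attaining = 0
        for seed in range(30):
            a, b, c = random_triple(3, "uniform", 777 + seed)
            ts = triangle_score(a, b, c).ts
            ms = median_bruteforce(a, b, c).score
            if 2 * ms != ts:
                continue
            attaining += 1
            assert unwind({"A": a, "B": b, "C": c}, ms)
        assert attaining >= 5  # the sample must actually exercise the property


class TestMsDelta:
    def test_strong_fusion_leaves_median_score_unchanged(self, fig4):
        from test_dcj import fusion_move

        a, b, c = fig4.triple()
        move = fusion_move(b, fig4.genomes["B'"], target="B")
        assert ms_delta_under_move(a, b, c, move) == 0

    def test_strong_move_on_identity_triple_raises_by_one(self):
        g = identity_genome(3)
        pair = find_strong_pair("A", g, g, g)
        _, move = apply_strong_dcj("A", g, g, g, pair)
        assert ms_delta_under_move(g, g, g, move) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_single_move_changes_score_by_at_most_one(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 4)
        a, b, c = random_triple(n, "uniform", 555 + seed)
        moves = list(enumerate_dcjs(a, "A"))
        move = moves[rng.randrange(len(moves))]
        delta = ms_delta_under_move(a, b, c, move)
        assert delta in (-1, 0, 1)
        inverse_delta = ms_delta_under_move(apply_dcj(a, move), b, c, move.inverse())
        assert delta + inverse_delta == 0

    def test_unknown_target_rejected(self, fig1):
        a, b, c = fig1.triple()
        move = next(enumerate_dcjs(a, target="Q"))
        with pytest.raises(GenomeError, match="target"):
            ms_delta_under_move(a, b, c, move)


def test_median_score_dispatch_consistency(fig3):
    assert median_score(*fig3.triple()) == 4
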