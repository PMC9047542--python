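import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from reosig import (
    ReversalPair,
    adjust_pvalues,
    consistency_significance,
    count_reo_support,
    find_reversal_pairs,
    intersect_reversal_pairs,
    maximum_matching_reduce,
    stable_pair_pvalue,
)
from reosig.pairs import A_GT_B, B_GT_A

from conftest import split_groups


def binomial_tail_oracle(n: int, m: int) -> float:
    """Exact upper tail P(X >= m) for X ~ Bin(n, 1/2) by enumeration."""
    total = sum(Fraction(math.comb(n, i)) for i in range(m, n + 1))
    return float(total / Fraction(2) ** n)


def max_matching_oracle(edges: list[tuple]) -> int:
    """Maximum matching size by brute-force subset enumeration."""
    best = 0
    for r in range(len(edges), 0, -1):
        if r <= best:
            break
        for subset in itertools.combinations(edges, r):
            genes = [g for e in subset for g in e]
            if len(set(genes)) == len(genes):
                best = max(best, r)
                break
    return best


class TestStablePairPvalue:
    def test_matches_enumeration_oracle_all_small_n(self):
        for n in range(26):
            for m in range(n + 1):
                assert stable_pair_pvalue(n, m) == pytest.approx(
                    binomial_tail_oracle(n, m), abs=1e-12
                )

    @pytest.mark.parametrize(
        "n,m,expected",
        [(1, 1, 0.5), (10, 10, 0.0009765625), (20, 15, 21700 / 1048576)],
    )
    def test_reference_values(self, n, m, expected):
        assert stable_pair_pvalue(n, m) == pytest.approx(expected, rel=1e-12)

    def test_numerically_stable_large_n(self):
        p = stable_pair_pvalue(10_000, 5_500)
        assert 0 < p < 1e-20

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            stable_pair_pvalue(5, 6)
        with pytest.raises(ValueError):
            stable_pair_pvalue(-1, 0)
        with pytest.raises(ValueError):
            stable_pair_pvalue(5, 2, p0=1.0)


class TestCountReoSupport:
    def test_direct_count(self):
        m = pd.DataFrame([[3, 5, 2], [1, 1, 4]], index=["a", "b"],
                         columns=list("xyz"), dtype=float)
        assert count_reo_support(m, ("a", "b")) == (3, 2, 0)

    def test_all_ties(self):
        m = pd.DataFrame([[2, 2], [2, 2]], index=["a", "b"],
                         columns=["x", "y"], dtype=float)
        assert count_reo_support(m, ("a", "b")) == (0, 0, 2)

    def test_monotone_transform_invariance(self, tiny_expr):
        before = count_reo_support(tiny_expr, ("GA", "GB"))
        after = count_reo_support(np.sqrt(tiny_expr) * 7 + 2, ("GA", "GB"))
        assert before == after

    def test_absent_gene_named_in_error(self, tiny_expr):
        with pytest.raises(KeyError, match="GZ"):
            count_reo_support(tiny_expr, ("GA", "GZ"))


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_single(self):
        assert adjust_pvalues([0.01], "bonferroni")[0] == pytest.approx(0.01)

    def test_bh_all_equal_unchanged(self):
        out = adjust_pvalues([0.2, 0.2, 0.2], "bh")
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


def _pair(a, b, d1=B_GT_A, d2=A_GT_B, p1=1e-6, p2=1e-6):
    return ReversalPair(gene_a=a, gene_b=b, direction_group1=d1,
                        direction_group2=d2, p_adj_group1=p1, p_adj_group2=p2)


class TestFindReversalPairs:
    def test_perfectly_stable_pair_has_all_success_tail(self):
        rng = np.random.default_rng(1)
        n = 60
        base = rng.lognormal(size=(1, n))
        g1 = pd.DataFrame(
            np.vstack([base * 0.5, base * 2.0]), index=["A", "B"],
            columns=[f"l{i}" for i in range(n)],
        )
        g2 = pd.DataFrame(
            np.vstack([base * 2.0, base * 0.5]), index=["A", "B"],
            columns=[f"h{i}" for i in range(n)],
        )
        revs, stats = find_reversal_pairs(g1, g2, ["A", "B"])
        assert len(revs) == 1
        assert stats["p_raw_group1"].iloc[0] == pytest.approx(0.5 ** 60)
        assert revs[0].high_risk_direction == A_GT_B

    def test_same_direction_in_both_groups_not_reversal(self):
        vals = pd.DataFrame([[5, 6, 7], [1, 2, 3]], index=["A", "B"],
                            columns=list("xyz"), dtype=float)
        revs, _ = find_reversal_pairs(vals, vals.rename(columns=str.upper),
                                      ["A", "B"])
        assert revs == []

    def test_planted_pairs_recovered(self, planted_study):
        expr, pheno, truth = planted_study
        low, high = split_groups(pheno)
        revs, _ = find_reversal_pairs(expr[low], expr[high], list(expr.index))
        found = {p.key for p in revs}
        planted = {frozenset(p) for p in truth.planted_pairs}
        assert len(found & planted) >= 14
        assert len(found - planted) <= 1

    def test_group_label_swap_exchanges_directions(self, planted_study):
        expr, pheno, _ = planted_study
        low, high = split_groups(pheno)
        fwd, _ = find_reversal_pairs(expr[low], expr[high], list(expr.index)[:40])
        rev, _ = find_reversal_pairs(expr[high], expr[low], list(expr.index)[:40])
        fwd_map = {p.key: p for p in fwd}
        assert {p.key for p in rev} == set(fwd_map)
        for p in rev:
            assert p.direction_group1 == fwd_map[p.key].direction_group2
            assert p.direction_group2 == fwd_map[p.key].direction_group1

    def test_too_few_candidates_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="two candidate"):
            find_reversal_pairs(tiny_expr, tiny_expr, ["GA"])


class TestIntersectAndConsistency:
    def test_identical_sets_identity(self):
        s = [_pair("A", "B"), _pair("C", "D")]
        assert intersect_reversal_pairs(s, s) == s

    def test_opposite_directions_excluded(self):
        s1 = [_pair("A", "B", d1=B_GT_A, d2=A_GT_B)]
        s2 = [_pair("A", "B", d1=A_GT_B, d2=B_GT_A)]
        with pytest.warns(UserWarning):
            assert intersect_reversal_pairs(s1, s2) == []

    def test_swapped_gene_order_same_pair(self):
        s1 = [_pair("A", "B", d1=B_GT_A, d2=A_GT_B)]
        s2 = [_pair("B", "A", d1=A_GT_B, d2=B_GT_A)]  # same assignment
        assert intersect_reversal_pairs(s1, s2) == s1

    def test_disjoint_sets_warn_empty(self):
        with pytest.warns(UserWarning):
            assert intersect_reversal_pairs([_pair("A", "B")],
                                            [_pair("C", "D")]) == []

    def test_consistency_all_concordant(self):
        s = [_pair(f"A{i}", f"B{i}") for i in range(10)]
        assert consistency_significance(s, s) == (10, 10, 0.0009765625)

    def test_consistency_no_shared_pairs(self):
        assert consistency_significance([_pair("A", "B")], [_pair("C", "D")]) \
            == (0, 0, 1.0)

    def test_consistency_partial_concordance(self):
        s1 = [_pair(f"A{i}", f"B{i}") for i in range(20)]
        s2 = s1[:15] + [
            _pair(f"A{i}", f"B{i}", d1=A_GT_B, d2=B_GT_A) for i in range(15, 20)
        ]
        k, c, p = consistency_significance(s1, s2)
        assert (k, c) == (20, 15)
        assert p == pytest.approx(21700 / 1048576, rel=1e-12)


class TestMaximumMatching:
    def test_single_edge(self):
        sig = maximum_matching_reduce([_pair("A", "B")])
        assert sig.pairs == [("A", "B")]

    def test_path_graph_keeps_ends(self):
        pairs = [_pair("A", "B"), _pair("B", "C"), _pair("C", "D")]
        sig = maximum_matching_reduce(pairs)
        assert sorted(frozenset(p) for p in sig.pairs) \
            == sorted([frozenset({"A", "B"}), frozenset({"C", "D"})])

    def test_triangle_keeps_one(self):
        pairs = [_pair("A", "B"), _pair("B", "C"), _pair("A", "C")]
        assert len(maximum_matching_reduce(pairs).pairs) == 1

    def test_orientation_follows_high_risk_direction(self):
        sig = maximum_matching_reduce([_pair("A", "B", d1=A_GT_B, d2=B_GT_A)])
        assert sig.pairs == [("B", "A")]  # B > A marks high risk

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            sig = maximum_matching_reduce([])
        assert len(sig) == 0 and sig.threshold == 0

    def test_matches_brute_force_on_random_graphs(self):
        """Matching size equals exhaustive enumeration; output is always
        gene-disjoint (checked on 200 random graphs of <= 12 edges)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_vertices = int(rng.integers(3, 9))
            max_edges = n_vertices * (n_vertices - 1) // 2
            n_edges = min(int(rng.integers(1, 13)), max_edges)
            edges = set()
            while len(edges) < n_edges:
                u, v = rng.integers(0, n_vertices, 2)
                if u != v:
                    edges.add((f"V{min(u, v)}", f"V{max(u, v)}"))
            pairs = [_pair(a, b, p1=float(rng.uniform()), p2=float(rng.uniform()))
                     for a, b in sorted(edges)]
            sig = maximum_matching_reduce(pairs)
            genes = [g for p in sig.pairs for g in p]
            assert len(set(genes)) == len(genes)
            assert len(sig.pairs) == max_matching_oracle(sorted(edges))

    def test_deterministic_across_runs(self):
        pairs = [_pair("A", "B", p1=0.001), _pair("B", "C", p1=0.0001),
                 _pair("C", "D", p1=0.002), _pair("D", "A", p1=0.003)]
        s1 = maximum_matching_reduce(pairs)
        s2 = maximum_matching_reduce(list(reversed(pairs)))
        assert s1.pairs == s2.pairs


class TestPvalueProperties:
    """Structural properties of the binomial stability tail."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(0, 500), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tail_bounded_and_decreasing_in_m(self, n, data):
        m = data.draw(self.st.integers(0, n))
        p = stable_pair_pvalue(n, m)
        assert 0.0 <= p <= 1.0
        if m > 0:
            assert p <= stable_pair_pvalue(n, m - 1) + 1e-15

    @given(st.integers(1, 200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_all_success_tail_is_power_of_half(self, n):
        assert stable_pair_pvalue(n, n) == pytest.approx(0.5 ** n, rel=1e-9)
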