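"""Reversal gene-pair discovery: binomial REO stability, intersection,
consistency assessment and maximum-matching redundancy removal.

A gene pair (A, B) is *stable* within a cohort of n informative samples
(ties excluded) if the majority ordering, observed in m of them, is
unlikely under chance: the upper binomial tail P(X >= m), X ~ Bin(n, 1/2),
falls below alpha after multiple-testing adjustment over all tested pairs.
A *reversal* pair is stable in both cohorts with opposite orderings —
the discriminative unit of the signature. Gene-disjointness of the final
signature is enforced by a maximum-cardinality matching on the graph whose
vertices are genes and whose edges are reversal pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .io import Signature

logger = logging.getLogger("reosig")

A_GT_B = "a_gt_b"
B_GT_A = "b_gt_a"
NO_DIRECTION = "none"


def stable_pair_pvalue(n: int, m: int, p0: float = 0.5) -> float:
    """Upper-tail binomial probability P(X >= m), X ~ Binomial(n, p0).

    The probability of observing a given ordering in at least m of n
    samples by chance; evaluated via the survival function, numerically
    stable for large n.
    """
    if n < 0 or m < 0 or m > n:
        raise ValueError(f"need 0 <= m <= n, got n={n}, m={m}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if m == 0:
        return 1.0
    return float(binom.sf(m - 1, n, p0))


def count_reo_support(
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    samples: list[str] | None = None,
) -> tuple[int, int, int]:
    """Count the ordering support of one pair: (n, m_a_gt_b, ties).

    n is the number of samples with a strict inequality between the two
    genes; ties are excluded from n and reported separately.
    """
    gene_a, gene_b = pair
    for g in (gene_a, gene_b):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    cols = samples if samples is not None else matrix.columns
    va = matrix.loc[gene_a, cols].to_numpy(dtype=float)
    vb = matrix.loc[gene_b, cols].to_numpy(dtype=float)
    ties = int((va == vb).sum())
    m = int((va > vb).sum())
    n = len(va) - ties
    return n, m, ties


def adjust_pvalues(p_raw, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg or Bonferroni)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return np.clip(multipletests(p, method=key)[1], 0.0, 1.0)


@dataclass(frozen=True)
class ReversalPair:
    """A gene pair stably ordered in both groups, in opposite directions.

    ``high_risk_direction`` is the ordering observed in the GBM-like
    cohort (group 2): ``a_gt_b`` means gene_a above gene_b marks high risk.
    """

    gene_a: str
    gene_b: str
    direction_group1: str
    direction_group2: str
    p_adj_group1: float
    p_adj_group2: float

    def __post_init__(self) -> None:
        if self.direction_group1 == self.direction_group2:
            raise ValueError("reversal pair requires opposite directions")
        if NO_DIRECTION in (self.direction_group1, self.direction_group2):
            raise ValueError("reversal pair requires a direction in both groups")

    @property
    def high_risk_direction(self) -> str:
        return self.direction_group2

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))

    def oriented(self) -> tuple[str, str]:
        """(first, second) such that first > second is the high-risk ordering."""
        if self.high_risk_direction == A_GT_B:
            return self.gene_a, self.gene_b
        return self.gene_b, self.gene_a


def _pair_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs ordering counts for a genes x samples value block.

    Returns (gt, ties): gt[i, j] = #samples with gene i > gene j;
    ties[i, j] = #samples with equality.
    """
    gt = (values[:, None, :] > values[None, :, :]).sum(axis=2)
    ties = (values[:, None, :] == values[None, :, :]).sum(axis=2)
    return gt, ties


def pair_stability_stats(matrix: pd.DataFrame, candidates: list[str]) -> pd.DataFrame:
    """Binomial REO stability of every candidate pair in one cohort.

    Returns one row per unordered pair (gene_a < gene_b lexicographically)
    with n, m_a_gt_b, ties, the majority direction and its raw p-value.
    """
    missing = [g for g in candidates if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    genes = sorted(candidates)
    values = matrix.loc[genes].to_numpy(dtype=float)
    gt, ties = _pair_counts(values)
    rows = []
    for i, j in combinations(range(len(genes)), 2):
        m_ab = int(gt[i, j])
        m_ba = int(gt[j, i])
        n = m_ab + m_ba
        if m_ab > m_ba:
            direction, m = A_GT_B, m_ab
        elif m_ba > m_ab:
            direction, m = B_GT_A, m_ba
        else:
            direction, m = NO_DIRECTION, m_ab
        p = stable_pair_pvalue(n, m) if n > 0 else 1.0
        rows.append(
            (genes[i], genes[j], n, m_ab, int(ties[i, j]), direction, p)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n", "m_a_gt_b", "ties", "direction", "p_raw"],
    )


def find_reversal_pairs(
    matrix_group1: pd.DataFrame,
    matrix_group2: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.01,
    adjust: str = "bh",
) -> tuple[list[ReversalPair], pd.DataFrame]:
    """Identify reversely stable pairs between two cohorts.

    Tests all C(k, 2) candidate pairs in each cohort, adjusts p-values
    within each cohort's family of tested pairs, and returns pairs
    significant in both (p_adj < alpha) with opposite majority directions.
    Group 2 is the GBM-like cohort; its ordering defines high risk.

    Returns (reversal pairs, full per-pair statistics table).
    """
    if len(set(candidates)) < 2:
        raise ValueError("need at least two candidate genes")
    stats1 = pair_stability_stats(matrix_group1, candidates)
    stats2 = pair_stability_stats(matrix_group2, candidates)
    stats = stats1.merge(
        stats2, on=["gene_a", "gene_b"], suffixes=("_group1", "_group2")
    )
    stats["p_adj_group1"] = adjust_pvalues(stats["p_raw_group1"], adjust)
    stats["p_adj_group2"] = adjust_pvalues(stats["p_raw_group2"], adjust)
    sig = (
        (stats["p_adj_group1"] < alpha)
        & (stats["p_adj_group2"] < alpha)
        & (stats["direction_group1"] != NO_DIRECTION)
        & (stats["direction_group2"] != NO_DIRECTION)
        & (stats["direction_group1"] != stats["direction_group2"])
    )
    reversals = [
        ReversalPair(
            gene_a=r.gene_a,
            gene_b=r.gene_b,
            direction_group1=r.direction_group1,
            direction_group2=r.direction_group2,
            p_adj_group1=r.p_adj_group1,
            p_adj_group2=r.p_adj_group2,
        )
        for r in stats[sig].itertuples()
    ]
    logger.info(
        "tested %d pairs, %d reversely stable at adjusted p < %g",
        len(stats), len(reversals), alpha,
    )
    return reversals, stats


def intersect_reversal_pairs(
    set1: list[ReversalPair], set2: list[ReversalPair]
) -> list[ReversalPair]:
    """Pairs present in both sets with identical direction assignments.

    Pair identity is unordered; directions are compared after orienting
    both occurrences the same way. Returns the set1 objects, in order.
    """
    def canon(p: ReversalPair) -> tuple:
        a, b = sorted((p.gene_a, p.gene_b))
        if a == p.gene_a:
            return (a, b, p.direction_group1, p.direction_group2)
        flip = {A_GT_B: B_GT_A, B_GT_A: A_GT_B}
        return (a, b, flip[p.direction_group1], flip[p.direction_group2])

    lookup = {canon(p) for p in set2}
    shared = [p for p in set1 if canon(p) in lookup]
    if not shared:
        warnings.warn("no reversal pairs shared between the two sets", stacklevel=2)
    return shared


def consistency_significance(
    set1: list[ReversalPair], set2: list[ReversalPair]
) -> tuple[int, int, float]:
    """Binomial significance of direction concordance between two pair sets.

    Of the k pairs found in both sets (unordered gene-pair identity),
    c agree in their per-group direction assignments; under chance each
    shared pair agrees with probability 1/2, so p = P(X >= c),
    X ~ Bin(k, 1/2). Returns (k, c, p); k = 0 gives p = 1 by convention.
    """
    keys2 = {p.key for p in set2}
    shared = [p for p in set1 if p.key in keys2]
    k = len(shared)
    if k == 0:
        return 0, 0, 1.0
    concordant = intersect_reversal_pairs(shared, set2)
    c = len(concordant)
    return k, c, stable_pair_pvalue(k, c)


def maximum_matching_reduce(
    pairs: list[ReversalPair], threshold: int | None = None
) -> Signature:
    """Reduce overlapping reversal pairs to a gene-disjoint signature.

    Genes are vertices, pairs are edges; a maximum-cardinality matching
    yields the largest set of pairs sharing no gene. Among multiple maximum
    matchings, edges with smaller worst-case adjusted p (then lexicographic
    gene order) are preferred, which makes the output deterministic.
    Retained pairs are oriented so gene_a > gene_b is the high-risk
    ordering; the vote threshold defaults to floor(n_pairs / 2).
    """
    if not pairs:
        warnings.warn("no reversal pairs to reduce; empty signature", stacklevel=2)
        return Signature(pairs=[], threshold=0)
    ranked = sorted(
        pairs,
        key=lambda p: (max(p.p_adj_group1, p.p_adj_group2), *sorted((p.gene_a, p.gene_b))),
    )
    graph = nx.Graph()
    n_edges = len(ranked)
    by_key: dict[frozenset[str], ReversalPair] = {}
    for rank, p in enumerate(ranked):
        if p.key in by_key:
            continue  # duplicate edge; keep the better-supported one
        by_key[p.key] = p
        graph.add_edge(p.gene_a, p.gene_b, weight=n_edges - rank)
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    matched = [by_key[frozenset(e)] for e in matching]
    oriented = sorted(p.oriented() for p in matched)
    if threshold is None:
        threshold = len(oriented) // 2
    logger.info(
        "maximum matching kept %d of %d pairs (threshold %d)",
        len(oriented), len(by_key), threshold,
    )
    return Signature(pairs=oriented, threshold=threshold)
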