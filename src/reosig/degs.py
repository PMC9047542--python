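"""Rank-based selection of differentially expressed genes.

Genes are ranked within each sample by expression (ascending, 1 = lowest,
average ranks on ties) after excluding genes whose median across the whole
training set is zero. Per group, the median of each gene's within-sample
ranks is taken; the genes with the largest median-rank differences between
the groups — k per direction — are the DEGs. Candidates for pair discovery
are the DEGs shared across training sets with the same direction.

Because only within-sample orderings enter, every result is invariant to
per-sample strictly increasing transforms of the expression values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("reosig")


def exclude_zero_median_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose median across all samples of the training set is 0.

    The median is taken over the pooled samples (both groups together).
    """
    medians = matrix.median(axis=1)
    keep = medians > 0
    if not keep.any():
        raise ValueError("all genes have zero median expression")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d zero-median genes", n_dropped)
    return matrix.loc[keep]


def rank_within_sample(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank genes within each sample, ascending, average ranks on ties."""
    degenerate = (matrix.nunique(axis=0) == 1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample(s) have all-equal expression; "
            "their ranks are all (G+1)/2",
            stacklevel=2,
        )
    return matrix.rank(axis=0, method="average", ascending=True)


@dataclass
class DegResult:
    """Median ranks per group and the selected differential genes."""

    group1: str
    group2: str
    #: per-gene: median_rank_group1, median_rank_group2, delta (g1 - g2)
    table: pd.DataFrame
    up_in_group1: list[str]
    up_in_group2: list[str]

    @property
    def selected(self) -> list[str]:
        return self.up_in_group1 + self.up_in_group2

    def direction(self, gene: str) -> str | None:
        if gene in self.up_in_group1:
            return self.group1
        if gene in self.up_in_group2:
            return self.group2
        return None


def select_top_degs(
    ranks: pd.DataFrame,
    pheno: pd.DataFrame,
    group1: str,
    group2: str,
    k_per_direction: int = 100,
    group_col: str = "group",
) -> DegResult:
    """Select the k genes per direction with the largest median-rank gap.

    ``delta = median_rank(group1) - median_rank(group2)``; the k genes with
    the largest positive delta are up in group1, the k most negative up in
    group2. Equal |delta| at the selection boundary is broken by
    lexicographic gene id for determinism.
    """
    samples1 = pheno.loc[pheno[group_col] == group1, "sample_id"]
    samples2 = pheno.loc[pheno[group_col] == group2, "sample_id"]
    samples1 = [s for s in samples1 if s in ranks.columns]
    samples2 = [s for s in samples2 if s in ranks.columns]
    if not samples1 or not samples2:
        raise ValueError(
            f"both groups must be non-empty in the expression matrix "
            f"({group1}: {len(samples1)}, {group2}: {len(samples2)})"
        )
    if 2 * k_per_direction > ranks.shape[0]:
        raise ValueError(
            f"k_per_direction={k_per_direction} needs 2k <= {ranks.shape[0]} genes"
        )
    med1 = ranks[samples1].median(axis=1)
    med2 = ranks[samples2].median(axis=1)
    delta = med1 - med2
    table = pd.DataFrame(
        {"median_rank_group1": med1, "median_rank_group2": med2, "delta": delta}
    )
    if (delta == 0).all():
        warnings.warn(
            "all median-rank deltas are zero; selection is degenerate and "
            "falls back to lexicographic order",
            stacklevel=2,
        )
    # sort by signed delta, lexicographic gene id as deterministic tie-break
    keyed = table.assign(_gene=table.index)
    order1 = keyed.sort_values(by=["delta", "_gene"], ascending=[False, True]).index
    order2 = keyed.sort_values(by=["delta", "_gene"], ascending=[True, True]).index
    up1 = list(order1[:k_per_direction])
    up2 = list(order2[:k_per_direction])
    return DegResult(
        group1=group1, group2=group2, table=table,
        up_in_group1=up1, up_in_group2=up2,
    )


def intersect_degs(results: list[DegResult]) -> list[str]:
    """Genes flagged in every result with the same direction.

    Directions are compared by the group name the gene is up-regulated in,
    so all results must use the same group labels.
    """
    if len(results) < 2:
        raise ValueError("need at least two DEG results to intersect")
    shared_up1 = set(results[0].up_in_group1)
    shared_up2 = set(results[0].up_in_group2)
    for r in results[1:]:
        shared_up1 &= set(r.up_in_group1)
        shared_up2 &= set(r.up_in_group2)
    common = sorted(shared_up1 | shared_up2)
    if not common:
        warnings.warn("no common DEGs across datasets", stacklevel=2)
    logger.info(
        "common DEGs: %d (%d up in %s, %d up in %s)",
        len(common), len(shared_up1), results[0].group1,
        len(shared_up2), results[0].group2,
    )
    return common
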