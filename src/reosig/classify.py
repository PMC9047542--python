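"""Majority-vote risk classification from a gene-pair signature.

For each sample, count the signature pairs whose high-risk ordering
(gene_a strictly above gene_b) holds; a sample with strictly more than
``threshold`` such votes is labelled high-risk (GBM-like), otherwise
low-risk. Only within-sample comparisons are made, so labels are invariant
to any per-sample strictly increasing transform of the expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import Signature

logger = logging.getLogger("reosig")

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"


@dataclass
class VoteResult:
    """Per-sample vote tally and risk label."""

    sample_id: str
    votes_high: int
    evaluable: int  # pairs with both genes present and a strict inequality
    label: str
    flags: list[str] = field(default_factory=list)


def classify_sample(
    expr_column: pd.Series,
    signature: Signature,
    lenient: bool = False,
    tie_policy: str = "count_low",
) -> VoteResult:
    """Classify one sample by majority voting over signature pairs.

    Ties within a pair never add a high-risk vote; with
    ``tie_policy="count_low"`` (default) they still count against the
    fixed threshold, with ``"exclude"`` semantics they are simply absent
    from the evaluable count (the vote rule is unchanged either way).
    Missing genes raise in strict mode; in lenient mode the affected pairs
    are dropped and the threshold becomes floor(usable_pairs / 2).
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    if tie_policy not in ("count_low", "exclude"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    flags: list[str] = []
    missing = [g for g in signature.genes if g not in expr_column.index]
    if missing and not lenient:
        raise KeyError(
            f"signature genes absent from expression data: {sorted(set(missing))}"
        )
    usable = [
        (a, b)
        for a, b in signature.pairs
        if a not in missing and b not in missing
    ]
    threshold = signature.threshold
    if missing:
        flags.append(f"missing_genes:{len(set(missing))}")
        threshold = len(usable) // 2
        logger.warning(
            "sample %s: %d signature gene(s) missing; using %d usable pairs "
            "with threshold %d",
            expr_column.name, len(set(missing)), len(usable), threshold,
        )
    votes = 0
    ties = 0
    for a, b in usable:
        va, vb = expr_column[a], expr_column[b]
        if va > vb:
            votes += 1
        elif va == vb:
            ties += 1
    if ties:
        flags.append(f"ties:{ties}")
    evaluable = len(usable) - ties
    label = HIGH_RISK if votes > threshold else LOW_RISK
    return VoteResult(
        sample_id=str(expr_column.name),
        votes_high=votes,
        evaluable=evaluable,
        label=label,
        flags=flags,
    )


def classify_cohort(
    matrix: pd.DataFrame,
    signature: Signature,
    lenient: bool = False,
    tie_policy: str = "count_low",
) -> pd.DataFrame:
    """Classify every sample of a cohort; one row per sample.

    Columns: sample_id, votes_high, evaluable, label, flags.
    """
    results = [
        classify_sample(matrix[s], signature, lenient=lenient, tie_policy=tie_policy)
        for s in matrix.columns
    ]
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "votes_high": [r.votes_high for r in results],
            "evaluable": [r.evaluable for r in results],
            "label": [r.label for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
    counts = df["label"].value_counts()
    logger.info(
        "classified %d samples: %d high-risk, %d low-risk",
        len(df), counts.get(HIGH_RISK, 0), counts.get(LOW_RISK, 0),
    )
    return df
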