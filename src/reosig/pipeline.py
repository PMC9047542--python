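"""End-to-end orchestration: discovery of a reversal-pair signature from
two labelled training datasets, and application of a signature to a cohort
with a survival report.

Discovery chain: zero-median exclusion -> within-sample ranking -> top-k
DEG selection per dataset -> direction-consistent DEG intersection ->
all-pairs reversal testing per dataset -> pair intersection -> binomial
consistency assessment -> maximum-matching reduction to a gene-disjoint
signature. Every intermediate count is logged and returned in the report.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import degs as _degs
from . import pairs as _pairs
from . import survival as _surv
from .classify import HIGH_RISK, LOW_RISK, classify_cohort
from .io import Signature

logger = logging.getLogger("reosig")


@dataclass
class PipelineConfig:
    """Settings shared by the discovery and application stages."""

    group_col: str = "group"
    group1: str = "LGG_like"  # low-risk reference group
    group2: str = "GBM_like"  # high-risk group; its REO defines high risk
    k_per_direction: int = 100
    alpha: float = 0.01
    adjust: str = "bh"
    lenient: bool = False
    horizon_months: float = 36.0
    metadata: dict[str, str] = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def _split_by_group(
    expr: pd.DataFrame, pheno: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    present = pheno[pheno["sample_id"].isin(expr.columns)]
    s1 = present.loc[present[config.group_col] == config.group1, "sample_id"]
    s2 = present.loc[present[config.group_col] == config.group2, "sample_id"]
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError(
            f"group split is empty ({config.group1}: {len(s1)}, "
            f"{config.group2}: {len(s2)})"
        )
    return expr[list(s1)], expr[list(s2)]


def run_discovery(
    datasets: list[tuple[pd.DataFrame, pd.DataFrame]],
    config: PipelineConfig | None = None,
) -> tuple[Signature, dict]:
    """Derive a gene-pair signature from two (expression, phenotype) sets.

    Returns the signature and a report dict with per-stage counts, the
    full pair-statistics tables, and the consistency assessment.
    """
    config = config or PipelineConfig()
    if len(datasets) < 2:
        raise ValueError("discovery requires at least two training datasets")
    report: dict = {"stages": {}}

    deg_results = []
    filtered = []
    with _stage("deg_selection"):
        for idx, (expr, pheno) in enumerate(datasets):
            kept = _degs.exclude_zero_median_genes(expr)
            ranks = _degs.rank_within_sample(kept)
            res = _degs.select_top_degs(
                ranks, pheno, config.group1, config.group2,
                k_per_direction=config.k_per_direction,
                group_col=config.group_col,
            )
            deg_results.append(res)
            filtered.append((kept, pheno))
            report["stages"][f"dataset{idx + 1}_genes_after_exclusion"] = len(kept)
        candidates = _degs.intersect_degs(deg_results)
        report["stages"]["common_degs"] = len(candidates)

    pair_sets = []
    with _stage("reversal_pairs"):
        for idx, (expr, pheno) in enumerate(filtered):
            m1, m2 = _split_by_group(expr, pheno, config)
            revs, stats = _pairs.find_reversal_pairs(
                m1, m2, candidates, alpha=config.alpha, adjust=config.adjust
            )
            pair_sets.append(revs)
            report["stages"][f"dataset{idx + 1}_reversal_pairs"] = len(revs)
            report[f"dataset{idx + 1}_pair_stats"] = stats

    with _stage("intersection"):
        shared = pair_sets[0]
        for other in pair_sets[1:]:
            shared = _pairs.intersect_reversal_pairs(shared, other)
        report["stages"]["intersected_reversal_pairs"] = len(shared)
        k, c, p_cons = _pairs.consistency_significance(pair_sets[0], pair_sets[1])
        report["consistency"] = {"shared": k, "concordant": c, "p": p_cons}

    with _stage("maximum_matching"):
        signature = _pairs.maximum_matching_reduce(shared)
        report["stages"]["signature_pairs"] = len(signature)
        report["stages"]["threshold"] = signature.threshold

    signature.metadata.update(config.metadata)
    logger.info("discovery report: %s", report["stages"])
    return signature, report


def run_apply(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    signature: Signature,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify a cohort and evaluate the risk split against survival.

    Returns the per-sample vote table and a report with Kaplan-Meier
    medians, the log-rank test, univariate/multivariate Cox results over
    the available covariates, and horizon-anchored AUCs of the vote score
    and of binary mutation covariates for comparison. Without survival
    columns in the phenotype table, only classification is performed.
    """
    config = config or PipelineConfig()
    with _stage("classification"):
        votes = classify_cohort(expr, signature, lenient=config.lenient)
    report: dict = {
        "n_high_risk": int((votes["label"] == HIGH_RISK).sum()),
        "n_low_risk": int((votes["label"] == LOW_RISK).sum()),
    }
    if not {"os_months", "event"}.issubset(pheno.columns):
        warnings.warn(
            "phenotype table lacks survival columns; classification-only output",
            stacklevel=2,
        )
        return votes, report

    merged = votes.merge(pheno, on="sample_id", how="inner").dropna(
        subset=["os_months", "event"]
    )
    with _stage("survival_eval"):
        high = merged[merged["label"] == HIGH_RISK]
        low = merged[merged["label"] == LOW_RISK]
        if len(high) and len(low):
            report["km_median_high"] = _surv.km_estimate(high).median
            report["km_median_low"] = _surv.km_estimate(low).median
            chi2, p = _surv.logrank(high, low)
            report["logrank"] = {"chi2": chi2, "p": p}
        else:
            warnings.warn("one risk group is empty; no log-rank test", stacklevel=2)

        available = [
            c for c in ("label", "age", "sex", "idh_status", "tert_status")
            if c in merged.columns
        ]
        usable = []
        for c in available:
            try:
                enc = _surv.encode_covariates(merged, [c])
            except (ValueError, TypeError):
                continue
            if enc[c].nunique() > 1:
                usable.append(c)
        if "label" in usable:
            report["cox_univariate"] = _surv.cox_fit(
                merged, ["label"], scope="univariate"
            )
            if len(usable) > 1:
                report["cox_multivariate"] = _surv.cox_fit(
                    merged, usable, scope="multivariate"
                )
        scores = merged.set_index("sample_id")["votes_high"].astype(float)
        rec = merged.set_index("sample_id")
        try:
            report["auc_votes"] = _surv.auc_at_horizon(
                scores, rec, horizon=config.horizon_months
            )
        except ValueError as exc:
            warnings.warn(f"AUC unavailable: {exc}", stacklevel=2)
        if "idh_status" in usable:
            idh_score = rec["idh_status"].map(_surv.COVARIATE_CODES["idh_status"])
            try:
                report["auc_idh"] = _surv.auc_at_horizon(
                    idh_score, rec, horizon=config.horizon_months
                )
            except ValueError:
                pass
    return votes, report


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a written artifact, for the machine-readable run summary."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
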