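"""Survival evaluation of risk groups.

Kaplan-Meier estimation, the two-group log-rank test, Cox proportional
hazards (univariate and multivariate, Efron tie handling) and a
horizon-anchored ROC AUC in which death before a fixed horizon (36 months
by default, i.e. 3-year survival) defines the positive reference class.
Estimation is delegated to lifelines / scikit-learn; this module fixes the
conventions (median as the first time S(t) <= 0.5, exclusion of samples
censored before the horizon, covariate encodings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import roc_auc_score

logger = logging.getLogger("reosig")

#: encodings for the categorical covariates the pipeline knows about; the
#: level coded 1 is the one whose hazard ratio is reported (e.g. IDH
#: wildtype vs mutant, high-risk vs low-risk)
COVARIATE_CODES: dict[str, dict[str, float]] = {
    "label": {"high_risk": 1.0, "low_risk": 0.0},
    "idh_status": {"wt": 1.0, "mut": 0.0},
    "tert_status": {"mut": 1.0, "wt": 0.0},
    "sex": {"M": 1.0, "F": 0.0},
    "grade": {"II": 2.0, "III": 3.0, "IV": 4.0},
}


def _check_times(time: pd.Series) -> None:
    if (time < 0).any():
        raise ValueError("negative survival time")


@dataclass
class KmCurve:
    """Product-limit survival curve."""

    timeline: np.ndarray  # event/censor times, ascending
    survival: np.ndarray  # S(t), non-increasing, starts at 1
    at_risk: np.ndarray
    median: float  # first time with S(t) <= 0.5; inf if never reached


def km_estimate(records: pd.DataFrame) -> KmCurve:
    """Kaplan-Meier estimate from a table with os_months and event columns."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    _check_times(records["os_months"])
    kmf = KaplanMeierFitter()
    kmf.fit(records["os_months"], records["event"])
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    return KmCurve(
        timeline=timeline,
        survival=survival,
        at_risk=at_risk,
        median=float(kmf.median_survival_time_),
    )


def logrank(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be non-empty")
    _check_times(records_a["os_months"])
    _check_times(records_b["os_months"])
    if records_a["event"].sum() + records_b["event"].sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(
        records_a["os_months"], records_b["os_months"],
        event_observed_A=records_a["event"], event_observed_B=records_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and p-values, one row per covariate.

    ``scope`` records whether covariates were fitted jointly or one at a
    time; ``status`` is "ok" or "failed:<reason>" when the partial
    likelihood did not converge.
    """

    scope: str
    table: pd.DataFrame  # covariate, hr, ci_lower, ci_upper, p
    status: str = "ok"


def encode_covariates(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix for the Cox model using the known encodings."""
    out = {}
    for cov in covariates:
        col = records[cov]
        if cov in COVARIATE_CODES and not pd.api.types.is_numeric_dtype(col):
            mapped = col.map(COVARIATE_CODES[cov])
            if mapped.isna().any():
                bad = sorted(col[mapped.isna()].unique())
                raise ValueError(f"covariate {cov!r}: unencodable levels {bad}")
            out[cov] = mapped.astype(float)
        else:
            out[cov] = pd.to_numeric(col)
    return pd.DataFrame(out, index=records.index)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    scope: str = "multivariate",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, lifelines backend).

    ``scope="multivariate"`` fits all covariates jointly;
    ``scope="univariate"`` fits each alone and stacks the rows.
    """
    if scope not in ("univariate", "multivariate"):
        raise ValueError(f"unknown scope {scope!r}")
    _check_times(records["os_months"])
    design = encode_covariates(records, covariates)
    for cov in covariates:
        if design[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
    n_events = int(records["event"].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariate(s)"
        )

    def _fit(cols: list[str]) -> pd.DataFrame:
        df = design[cols].assign(
            os_months=records["os_months"].to_numpy(),
            event=records["event"].to_numpy(),
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="os_months", event_col="event")
        summ = cph.summary
        return pd.DataFrame(
            {
                "covariate": summ.index,
                "hr": summ["exp(coef)"].to_numpy(),
                "ci_lower": summ["exp(coef) lower 95%"].to_numpy(),
                "ci_upper": summ["exp(coef) upper 95%"].to_numpy(),
                "p": summ["p"].to_numpy(),
            }
        )

    try:
        if scope == "multivariate":
            table = _fit(covariates)
        else:
            table = pd.concat(
                [_fit([c]) for c in covariates], ignore_index=True
            )
    except ConvergenceError as exc:
        logger.warning("Cox fit failed to converge: %s", exc)
        return CoxResult(scope=scope, table=pd.DataFrame(), status=f"failed:{exc}")
    return CoxResult(scope=scope, table=table.reset_index(drop=True))


def auc_at_horizon(
    scores: pd.Series,
    records: pd.DataFrame,
    horizon: float = 36.0,
) -> float:
    """ROC AUC of a risk score against survival past a fixed horizon.

    Positive reference: death observed before the horizon. Negative
    reference: follow-up (event or censoring) beyond the horizon. Samples
    censored before the horizon carry no reference label and are excluded.
    AUC is the Mann-Whitney concordance probability, ties counted 0.5.
    """
    records = records.loc[scores.index]
    _check_times(records["os_months"])
    positive = (records["os_months"] < horizon) & (records["event"] == 1)
    negative = records["os_months"] >= horizon
    keep = positive | negative
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "AUC at %g months: excluded %d sample(s) censored before horizon",
            horizon, n_excluded,
        )
    y = positive[keep].astype(int)
    if y.nunique() < 2:
        raise ValueError(
            f"one reference class is empty at horizon {horizon} months"
        )
    return float(roc_auc_score(y, scores[keep]))
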