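"""Synthetic two-cohort expression studies with known ground truth.

The generator emulates the statistical structure that reversal-pair
discovery assumes: two groups of samples (an LGG-like low-risk group and a
GBM-like high-risk group) whose expression matrix contains

* planted reversal pairs — gene pairs whose within-sample ordering is
  stable inside each group but points in opposite directions between
  groups, at a controlled stability level;
* planted differential genes — genes shifted on the log scale in one
  group, so their within-sample ranks separate the groups;
* background genes with no group effect;

plus per-sample survival times with a class-dependent hazard, independent
right censoring, and binary mutation labels correlated with class.

Expression model: gene g in sample s has value ``exp(mu + eps)`` with
``eps ~ N(0, noise_sd)`` i.i.d. For a planted pair the two genes share a
baseline rung and receive group-specific offsets ``+/- delta``; ``delta``
is derived in closed form from ``noise_sd`` and the target stability via
the normal CDF, so the per-sample probability of the planted ordering
equals the target. Rungs of different pairs are spaced more than
``2 * delta`` apart, and background plus differential genes share a band
strictly above every rung's window, so no gene can systematically reverse
against a pair gene: the only planted-pair-adjacent reversals are the
planted pairs themselves. Differential genes do reverse against the genes
they cross when shifted — which is the signal the method is built on. The planted structure (which genes pair up, orderings per
group, which genes are differential) is a deterministic function of the
config dimensions, so two simulations of the same shape share their ground
truth and can serve as twin training sets; only band placements, noise,
survival and labels depend on the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtri

LOW_GROUP = "LGG_like"
HIGH_GROUP = "GBM_like"

# named sub-streams: one per stochastic component, so adding or resampling
# one component never perturbs another
_STREAM_EXPRESSION = 0
_STREAM_SURVIVAL = 1
_STREAM_CENSORING = 2
_STREAM_LABELS = 3


@dataclass
class SimulationConfig:
    """Parameters of a synthetic two-cohort study.

    ``reversal_stability`` is the target per-sample probability that a
    planted pair shows its group's ordering, in (0.5, 1]. ``deg_rank_shift``
    is the log-scale mean shift of planted differential genes.
    ``hazard_ratio_high_vs_low`` multiplies the exponential hazard of the
    GBM-like class; ``baseline_median_os_months`` is the median survival
    of the low-risk class.
    """

    n_genes: int = 200
    n_samples_per_group: int = 60
    n_planted_reversal_pairs: int = 15
    reversal_stability: float = 0.98
    n_planted_degs: int = 30
    deg_rank_shift: float = 1.5
    noise_sd: float = 0.5
    hazard_ratio_high_vs_low: float = 4.0
    baseline_median_os_months: float = 60.0
    censor_fraction: float = 0.2
    seed: int = 0
    # class-conditional label frequencies (probability of the mutant state)
    idh_mut_freq: dict[str, float] = field(
        default_factory=lambda: {"low": 0.85, "high": 0.15}
    )
    tert_mut_freq: dict[str, float] = field(
        default_factory=lambda: {"low": 0.80, "high": 0.85}
    )

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if 2 * self.n_planted_reversal_pairs + self.n_planted_degs > self.n_genes:
            raise ValueError(
                "infeasible config: 2*n_planted_reversal_pairs + n_planted_degs "
                f"= {2 * self.n_planted_reversal_pairs + self.n_planted_degs} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if not 0.5 < self.reversal_stability <= 1.0:
            raise ValueError("reversal_stability must lie in (0.5, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.baseline_median_os_months <= 0:
            raise ValueError("baseline median survival must be positive")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: pairs, differential genes, true risk class."""

    #: (gene_a, gene_b) such that gene_a > gene_b in the GBM-like group
    #: and gene_a < gene_b in the LGG-like group
    planted_pairs: list[tuple[str, str]]
    #: (gene_id, group in which the gene is up-regulated)
    planted_degs: list[tuple[str, str]]
    #: per-sample true class, "high" or "low", indexed by sample id
    true_class: pd.Series


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _pair_offset(stability: float, noise_sd: float) -> float:
    """Half-separation delta on the log scale for a target stability.

    The ordering statistic of a pair is N(2*delta, 2*noise_sd^2); solving
    P(>0) = stability gives delta = noise_sd * z / sqrt(2). Stability 1 (or
    zero noise) degenerates to a deterministic ordering.
    """
    if noise_sd == 0:
        return 1.0
    s = min(stability, 1.0 - 1e-12)
    return noise_sd * float(ndtri(s)) / np.sqrt(2.0)


def planted_structure(config: SimulationConfig) -> GroundTruth:
    """The deterministic planted layout implied by the config dimensions.

    Pair k occupies genes (2k, 2k+1); differential genes follow, the first
    half up-regulated in the LGG-like group, the rest in the GBM-like
    group. ``true_class`` here is by construction: all LGG-like samples
    are low risk, all GBM-like samples high risk.
    """
    genes = _gene_ids(config.n_genes)
    pairs = [
        (genes[2 * k], genes[2 * k + 1])
        for k in range(config.n_planted_reversal_pairs)
    ]
    deg_start = 2 * config.n_planted_reversal_pairs
    degs = []
    for j in range(config.n_planted_degs):
        group = LOW_GROUP if j < config.n_planted_degs // 2 else HIGH_GROUP
        degs.append((genes[deg_start + j], group))
    n = config.n_samples_per_group
    sample_ids = [f"L{i + 1:04d}" for i in range(n)] + [
        f"H{i + 1:04d}" for i in range(n)
    ]
    true_class = pd.Series(
        ["low"] * n + ["high"] * n, index=sample_ids, name="true_class"
    )
    return GroundTruth(planted_pairs=pairs, planted_degs=degs, true_class=true_class)


def simulate_survival(
    true_class: pd.Series,
    hr: float,
    baseline_median: float,
    censor_fraction: float,
    seed: int | np.random.Generator,
    censor_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with class-dependent hazard and uniform censoring.

    Event times are exponential; the "high" class hazard is ``hr`` times
    the "low" class hazard, whose median is ``baseline_median`` months.
    Censoring times are uniform on (0, c_max) with c_max calibrated so the
    expected censored fraction matches ``censor_fraction``; censoring is
    independent of class. Returns a DataFrame with os_months and event.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng([_STREAM_SURVIVAL, seed])
    if censor_rng is None:
        if isinstance(seed, np.random.Generator):
            censor_rng = rng
        else:
            censor_rng = np.random.default_rng([_STREAM_CENSORING, seed])

    rate_low = np.log(2.0) / baseline_median
    rates = np.where(true_class.to_numpy() == "high", hr * rate_low, rate_low)
    t_event = rng.exponential(1.0 / rates)

    if censor_fraction == 0:
        return pd.DataFrame(
            {"os_months": t_event, "event": np.ones(len(t_event), dtype=int)},
            index=true_class.index,
        )

    def expected_censored(c: float) -> float:
        # P(C < T) for C ~ U(0, c), T ~ Exp(rate), averaged over samples
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    hi = baseline_median
    while expected_censored(hi) > censor_fraction:
        hi *= 2.0
    c_max = brentq(
        lambda c: expected_censored(c) - censor_fraction, 1e-9 * hi, hi
    )
    t_censor = censor_rng.uniform(0.0, c_max, size=len(t_event))
    os_months = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {"os_months": os_months, "event": event}, index=true_class.index
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, phenotype table, ground truth).

    Deterministic given ``config.seed``. Expression is genes x samples,
    strictly positive; the phenotype table carries group, survival,
    mutation labels, grade, age and sex.
    """
    config.validate()
    truth = planted_structure(config)
    genes = _gene_ids(config.n_genes)
    n = config.n_samples_per_group
    sample_ids = list(truth.true_class.index)
    is_high = (truth.true_class == "high").to_numpy()

    rng = np.random.default_rng([_STREAM_EXPRESSION, config.seed])
    delta = _pair_offset(config.reversal_stability, config.noise_sd)

    # Layered log-scale layout. Each planted pair straddles its own
    # baseline rung; rungs are spaced more than 2*delta apart so genes of
    # different pairs keep the same ordering in both groups and never form
    # spurious reversals. Background genes occupy a band strictly below
    # every rung's +/-delta window, differential genes a band strictly
    # above, so neither can reverse against a pair gene either.
    margin = 2.0 * config.noise_sd + 0.1
    gap = 2.0 * delta + margin
    half_window = delta + margin
    n_pairs = config.n_planted_reversal_pairs
    top_rung = gap * max(n_pairs - 1, 0)
    band_width = 4.0

    mu = np.zeros((config.n_genes, 2 * n))
    for k in range(n_pairs):
        ia, ib = 2 * k, 2 * k + 1
        rung = gap * k
        # LGG-like: b > a; GBM-like: a > b (the high-risk ordering)
        mu[ia, ~is_high] = rung - delta
        mu[ib, ~is_high] = rung + delta
        mu[ia, is_high] = rung + delta
        mu[ib, is_high] = rung - delta
    # Differential and background genes share one band above every rung's
    # window: interleaved backgrounds give a shifted gene other genes to
    # cross, so planted differential genes acquire large rank shifts.
    deg_start = 2 * n_pairs
    n_band = config.n_genes - deg_start
    band_lo = top_rung + half_window if n_pairs else 0.0
    band_base = rng.uniform(band_lo, band_lo + band_width, size=n_band)
    mu[deg_start:] = band_base[:, None]
    for j, (_, up_group) in enumerate(truth.planted_degs):
        idx = deg_start + j
        shift_cols = is_high if up_group == HIGH_GROUP else ~is_high
        mu[idx, shift_cols] += config.deg_rank_shift

    noise = rng.normal(0.0, config.noise_sd, size=mu.shape)
    logx = mu + noise
    # Enforce the generator's stability contract: the empirical
    # within-group fraction obeying each planted ordering must not fall
    # below reversal_stability - 0.03. Pairs that miss the floor by
    # sampling chance have their two noise rows redrawn (conditional
    # sampling; deterministic given the seed).
    floor = config.reversal_stability - 0.03 - 1e-12
    for k in range(n_pairs):
        ia, ib = 2 * k, 2 * k + 1
        for _ in range(10_000):
            frac_low = float((logx[ib, ~is_high] > logx[ia, ~is_high]).mean())
            frac_high = float((logx[ia, is_high] > logx[ib, is_high]).mean())
            if frac_low >= floor and frac_high >= floor:
                break
            fresh = rng.normal(0.0, config.noise_sd, size=(2, 2 * n))
            logx[ia] = mu[ia] + fresh[0]
            logx[ib] = mu[ib] + fresh[1]
        else:  # pragma: no cover - unreachable for valid configs
            raise RuntimeError(f"could not satisfy stability floor for pair {k}")
    expr = pd.DataFrame(np.exp(logx), index=genes, columns=sample_ids)

    surv = simulate_survival(
        truth.true_class,
        config.hazard_ratio_high_vs_low,
        config.baseline_median_os_months,
        config.censor_fraction,
        config.seed,
    )

    lab_rng = np.random.default_rng([_STREAM_LABELS, config.seed])
    cls = np.where(is_high, "high", "low")
    idh_p = np.vectorize(config.idh_mut_freq.get)(cls).astype(float)
    tert_p = np.vectorize(config.tert_mut_freq.get)(cls).astype(float)
    idh = np.where(lab_rng.uniform(size=2 * n) < idh_p, "mut", "wt")
    tert = np.where(lab_rng.uniform(size=2 * n) < tert_p, "mut", "wt")
    # grade echoes class: low-risk samples are grade II/III, high-risk
    # samples mostly grade IV
    grade_low = np.where(lab_rng.uniform(size=2 * n) < 0.5, "II", "III")
    grade_high = np.where(lab_rng.uniform(size=2 * n) < 0.9, "IV", "III")
    grade = np.where(is_high, grade_high, grade_low)
    age = np.clip(
        lab_rng.normal(np.where(is_high, 55.0, 45.0), 12.0), 18.0, 90.0
    ).round(1)
    sex = np.where(lab_rng.uniform(size=2 * n) < 0.55, "M", "F")

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_high, HIGH_GROUP, LOW_GROUP),
            "os_months": surv["os_months"].to_numpy(),
            "event": surv["event"].to_numpy(),
            "tert_status": tert,
            "idh_status": idh,
            "grade": grade,
            "age": age,
            "sex": sex,
        }
    )
    return expr, pheno, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the ground truth as a small TSV (sectioned by kind)."""
    lines = ["kind\tfield1\tfield2"]
    for a, b in truth.planted_pairs:
        lines.append(f"pair\t{a}\t{b}")
    for g, grp in truth.planted_degs:
        lines.append(f"deg\t{g}\t{grp}")
    for sid, cls in truth.true_class.items():
        lines.append(f"class\t{sid}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n")
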