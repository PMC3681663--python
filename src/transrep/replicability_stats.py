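"""Replication-rate statistics, null expectations and publication-bias bounds.

A replication attempt is successful when the same risk allele found in
the discovery study reaches p < alpha in the replication study.  Under
the null of no shared association the expected success rate is alpha
(the convention used for headline expected counts) or alpha/2 when the
same-direction requirement is taken into account; both conventions are
exposed.

The publication-bias bound asks: if every observed success were a type I
error, how large a pool of (mostly unreported) attempts would that
imply?  With success probability alpha * p_same_dir per null attempt,
k observed successes imply a pool of k / (alpha * p_same_dir), with a
Poisson confidence interval on k scaled the same way.  A complementary
lower bound divides the observed successes by the gathered attempts
plus the maximum conceivable number of unreported ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicabilitySummary",
    "BiasBound",
    "round_half_up",
    "replication_rate",
    "expected_null_count",
    "binomial_null_test",
    "effective_replicability",
    "direction_consistency_test",
    "disease_heterogeneity_test",
    "publication_bias_bounds",
    "summarize_replicability",
]


@dataclass(frozen=True)
class ReplicabilitySummary:
    """Observed and expected replication counts at a significance level."""

    n_attempts: int
    n_success: int
    rate: float
    alpha: float
    expected_null: float
    p_binomial: float
    expected_power: float | None = None
    effective_rate: float | None = None
    effective_capped: bool = False


@dataclass(frozen=True)
class BiasBound:
    """Bounds on replicability under extreme publication-bias scenarios."""

    observed: int
    alpha: float
    p_same_dir: float
    implied_pool: float
    implied_unreported: float
    pool_ci_low: float
    pool_ci_high: float
    n_gathered: int
    n_unreported_max: int
    lower_bound_rate: float


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention; raw values are
    always kept alongside rounded ones)."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum,
                                               rounding=ROUND_HALF_UP))


def replication_rate(n_success: int, n_attempts: int) -> float:
    """Fraction of successful attempts (exact ratio)."""
    if n_attempts <= 0:
        raise ValueError("n_attempts must be positive")
    if not 0 <= n_success <= n_attempts:
        raise ValueError("n_success must lie in [0, n_attempts]")
    return n_success / n_attempts


def expected_null_count(n_attempts: int, alpha: float,
                        convention: str = "any_direction") -> float:
    """Expected successes under the no-association null.

    ``any_direction`` gives n * alpha (the headline convention);
    ``same_direction`` gives n * alpha / 2, accounting for the
    requirement that the same risk allele be observed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if convention == "any_direction":
        return n_attempts * alpha
    if convention == "same_direction":
        return n_attempts * alpha / 2.0
    raise ValueError(f"unknown null convention: {convention!r}")


def binomial_null_test(n_success: int, n_attempts: int, alpha: float) -> float:
    """Exact one-sided upper-tail binomial p-value P[X >= k | n, alpha]."""
    if n_attempts <= 0 or not 0 <= n_success <= n_attempts:
        raise ValueError("invalid counts")
    return stats.binomtest(n_success, n_attempts, alpha,
                           alternative="greater").pvalue


def effective_replicability(n_success: float, expected_power: float):
    """Observed successes over power-expected successes.

    Returns ``(rate, capped)`` where ``capped`` flags values above 1
    (possible by chance or when power inputs are misspecified); the raw
    ratio is always returned.
    """
    if expected_power <= 0:
        raise ValueError("expected_power must be positive")
    rate = n_success / expected_power
    return rate, rate > 1.0


def direction_consistency_test(n_same_direction: int, n_attempts: int):
    """Share of attempts with the discovery risk allele, tested against 0.5.

    Returns ``(fraction, p)`` with an exact two-sided binomial test.
    """
    if n_attempts <= 0 or not 0 <= n_same_direction <= n_attempts:
        raise ValueError("invalid counts")
    result = stats.binomtest(n_same_direction, n_attempts, 0.5,
                             alternative="two-sided")
    return n_same_direction / n_attempts, result.pvalue


def disease_heterogeneity_test(counts: pd.DataFrame, n_resamples: int = 10_000,
                               seed: int | None = None):
    """Chi-square homogeneity test of replication rates across diseases.

    ``counts`` needs columns (disease, n_success, n_attempts).  Diseases
    with zero attempts are dropped (and reported).  When any expected
    cell is below 5 the p-value is computed by Monte-Carlo permutation
    of the pooled success labels across diseases (>= ``n_resamples``
    resamples) instead of the asymptotic distribution.

    Returns a dict with statistic, dof, p_value, method, dropped.
    """
    work = counts.copy()
    dropped = list(work.loc[work["n_attempts"] <= 0, "disease"])
    work = work[work["n_attempts"] > 0]
    if len(work) < 2:
        raise ValueError("need at least two diseases with attempts")
    success = work["n_success"].to_numpy(dtype=int)
    attempts = work["n_attempts"].to_numpy(dtype=int)
    if np.any(success < 0) or np.any(success > attempts):
        raise ValueError("invalid counts")
    table = np.column_stack([success, attempts - success])
    # degenerate all-success or all-failure tables carry no signal
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return {"statistic": 0.0, "dof": len(work) - 1, "p_value": 1.0,
                "method": "degenerate", "dropped": dropped}
    stat, p_asym, dof, expected = stats.chi2_contingency(table,
                                                         correction=False)
    if (expected >= 5).all():
        return {"statistic": float(stat), "dof": int(dof),
                "p_value": float(p_asym), "method": "chi2",
                "dropped": dropped}
    rng = np.random.default_rng(seed)
    pooled = np.arange(len(work)).repeat(attempts)
    outcomes = np.zeros(attempts.sum(), dtype=bool)
    outcomes[: success.sum()] = True
    count_extreme = 0
    for _ in range(n_resamples):
        rng.shuffle(outcomes)
        sim_success = np.bincount(pooled[outcomes], minlength=len(work))
        sim_table = np.column_stack([sim_success, attempts - sim_success])
        sim_stat, *_ = stats.chi2_contingency(sim_table, correction=False)
        if sim_stat >= stat - 1e-12:
            count_extreme += 1
    p_mc = (1 + count_extreme) / (1 + n_resamples)
    return {"statistic": float(stat), "dof": int(dof), "p_value": float(p_mc),
            "method": "permutation", "dropped": dropped}


def _poisson_ci(k: int, level: float = 0.95):
    """Garwood exact Poisson confidence interval from chi-square quantiles."""
    tail = (1.0 - level) / 2.0
    low = 0.0 if k == 0 else stats.chi2.ppf(tail, 2 * k) / 2.0
    high = stats.chi2.ppf(1.0 - tail, 2 * (k + 1)) / 2.0
    return low, high


def publication_bias_bounds(observed: int, alpha: float, p_same_dir: float,
                            n_gathered: int, n_unreported_max: int,
                            ci_level: float = 0.95,
                            ci_method: str = "garwood") -> BiasBound:
    """Bounding arithmetic for the extreme publication-bias scenario.

    ``implied_pool`` is the attempt-pool size needed for all ``observed``
    successes to be same-direction type I errors; its CI treats the
    observed count as Poisson (``garwood`` exact by default,
    ``normal`` for the k +/- 1.96*sqrt(k) approximation).
    ``lower_bound_rate`` is observed / (n_gathered + n_unreported_max).
    """
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if alpha * p_same_dir <= 0:
        raise ValueError("alpha * p_same_dir must be positive")
    scale = 1.0 / (alpha * p_same_dir)
    implied_pool = observed * scale
    if ci_method == "garwood":
        low, high = _poisson_ci(observed, ci_level)
    elif ci_method == "normal":
        z = stats.norm.ppf(1 - (1 - ci_level) / 2)
        half = z * np.sqrt(observed)
        low, high = max(observed - half, 0.0), observed + half
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    denom = n_gathered + n_unreported_max
    lower_rate = observed / denom if denom > 0 else float("nan")
    return BiasBound(
        observed=observed,
        alpha=alpha,
        p_same_dir=p_same_dir,
        implied_pool=implied_pool,
        implied_unreported=implied_pool - observed,
        pool_ci_low=low * scale,
        pool_ci_high=high * scale,
        n_gathered=n_gathered,
        n_unreported_max=n_unreported_max,
        lower_bound_rate=lower_rate,
    )


def summarize_replicability(attempts: pd.DataFrame, alpha: float = 0.05,
                            convention: str = "any_direction",
                            ) -> ReplicabilitySummary:
    """Summarize a powered attempts table at significance level alpha.

    Success is recomputed as same-direction (or_replication > 1 after
    risk-allele referencing) AND p_replication < alpha.  When a filled
    ``power`` column is present the power-expected count and effective
    rate are included.
    """
    n = len(attempts)
    if n == 0:
        raise ValueError("no attempts to summarize")
    direction_same = attempts["or_replication"].to_numpy(dtype=float) > 1.0
    significant = attempts["p_replication"].to_numpy(dtype=float) < alpha
    k = int((direction_same & significant).sum())
    expected_power = None
    effective = None
    capped = False
    if "power" in attempts.columns and attempts["power"].notna().all():
        expected_power = float(attempts["power"].sum())
        effective, capped = effective_replicability(k, expected_power)
    return ReplicabilitySummary(
        n_attempts=n,
        n_success=k,
        rate=replication_rate(k, n),
        alpha=alpha,
        expected_null=expected_null_count(n, alpha, convention),
        p_binomial=binomial_null_test(k, n, alpha),
        expected_power=expected_power,
        effective_rate=effective,
        effective_capped=capped,
    )
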