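"""Replication power for a case-control allelic association test.

The model is log-additive: a risk allele with odds ratio ``psi`` per
copy and frequency ``raf`` among controls.  Power is evaluated for a
two-proportion z-test on allele counts (2 alleles per individual), i.e.
the classical allelic chi-square test, at a two-sided level ``alpha``.

Disease prevalence is ignored: the control risk-allele frequency is
taken as the population frequency (the standard low-prevalence
approximation).  Under the log-additive model the case allele frequency
is

    p1 = psi * p0 / (1 + p0 * (psi - 1))

and the non-centrality of the test statistic is (p1 - p0) / SE_alt with

    SE_alt = sqrt( p1*(1-p1)/(2*n_cases) + p0*(1-p0)/(2*n_controls) ).

By default power counts only *same-direction* significance - the
probability that the test is significant at two-sided alpha AND the
estimated effect has the sign of log(psi) - because a replication is
declared successful only when the same risk allele reaches the
threshold.  At psi = 1 this equals alpha/2 by continuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PowerInput",
    "case_allele_frequency",
    "noncentrality",
    "replication_power",
    "log_or_standard_error",
    "attach_power",
    "expected_replications",
]


@dataclass(frozen=True)
class PowerInput:
    """Inputs for one replication-power evaluation.

    or_true : discovery odds ratio psi (> 0, risk-allele referenced)
    raf     : risk-allele frequency in the replication population, in (0, 1)
    n_cases, n_controls : replication sample sizes (individuals)
    alpha   : two-sided significance level of the replication test
    """

    or_true: float
    raf: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def power(self, direction: str = "same") -> float:
        return float(
            replication_power(
                self.or_true, self.raf, self.n_cases, self.n_controls,
                alpha=self.alpha, direction=direction,
            )
        )


def case_allele_frequency(or_true, raf):
    """Risk-allele frequency among cases under the log-additive model."""
    or_true = np.asarray(or_true, dtype=float)
    p0 = np.asarray(raf, dtype=float)
    return or_true * p0 / (1.0 + p0 * (or_true - 1.0))


def noncentrality(or_true, raf, n_cases, n_controls):
    """Signed non-centrality (p1 - p0) / SE_alt of the allelic z-test.

    Allele counts are 2 per individual, hence the 2*n denominators.
    """
    p0 = np.asarray(raf, dtype=float)
    p1 = case_allele_frequency(or_true, p0)
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    se_alt = np.sqrt(
        p1 * (1.0 - p1) / (2.0 * n_cases) + p0 * (1.0 - p0) / (2.0 * n_controls)
    )
    return (p1 - p0) / se_alt


def _validate(or_true, raf, n_cases, n_controls, alpha) -> None:
    or_true = np.asarray(or_true, dtype=float)
    raf = np.asarray(raf, dtype=float)
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    if np.any(or_true <= 0):
        raise ValueError("odds ratio must be positive")
    if np.any((raf <= 0) | (raf >= 1)):
        raise ValueError("risk-allele frequency must lie strictly in (0, 1)")
    if np.any(n_cases <= 0) or np.any(n_controls <= 0):
        raise ValueError("sample sizes must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")


def replication_power(or_true, raf, n_cases, n_controls, alpha=0.05,
                      direction="same"):
    """Probability that the replication allelic test succeeds.

    direction="same" (default): significant at two-sided ``alpha`` and
    with the estimated effect on the side of log(or_true); returns
    alpha/2 at or_true = 1.  direction="any": significance regardless
    of sign (adds the opposite-tail mass).

    Accepts scalars or broadcastable arrays; returns a float for scalar
    input.
    """
    _validate(or_true, raf, n_cases, n_controls, alpha)
    if direction not in ("same", "any"):
        raise ValueError("direction must be 'same' or 'any'")
    ncp = noncentrality(or_true, raf, n_cases, n_controls)
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    power = norm.cdf(np.abs(ncp) - z_crit)
    if direction == "any":
        power = power + norm.cdf(-np.abs(ncp) - z_crit)
    if np.ndim(power) == 0:
        return float(power)
    return power


def log_or_standard_error(raf, or_true, n_cases, n_controls):
    """Woolf standard error of the estimated log odds ratio from a 2x2
    allele-count table expected under the log-additive model.

    1/(2*n_cases*p1*(1-p1)) + 1/(2*n_controls*p0*(1-p0)) equals the
    usual sum of reciprocal cell counts.
    """
    p0 = np.asarray(raf, dtype=float)
    p1 = case_allele_frequency(or_true, p0)
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    var = 1.0 / (2.0 * n_cases * p1 * (1.0 - p1)) + 1.0 / (
        2.0 * n_controls * p0 * (1.0 - p0)
    )
    return np.sqrt(var)


def attach_power(attempts: pd.DataFrame, alpha: float = 0.05,
                 direction: str = "same",
                 or_column: str = "or_discovery") -> pd.DataFrame:
    """Return a copy of ``attempts`` with the ``power`` column filled.

    Requires columns ``or_column`` (discovery OR, risk-allele
    referenced), ``raf_replication_pop``, ``n_cases``, ``n_controls``.
    The discovery OR is folded to max(OR, 1/OR): power depends only on
    the effect magnitude once alleles are referenced consistently.
    """
    required = {or_column, "raf_replication_pop", "n_cases", "n_controls"}
    missing = required - set(attempts.columns)
    if missing:
        raise ValueError(f"attempts table missing columns: {sorted(missing)}")
    out = attempts.copy()
    psi = out[or_column].to_numpy(dtype=float)
    psi = np.maximum(psi, 1.0 / psi)
    out["power"] = replication_power(
        psi,
        out["raf_replication_pop"].to_numpy(dtype=float),
        out["n_cases"].to_numpy(dtype=float),
        out["n_controls"].to_numpy(dtype=float),
        alpha=alpha,
        direction=direction,
    )
    return out


def expected_replications(attempts: pd.DataFrame, alpha: float = 0.05,
                          direction: str = "same",
                          or_column: str = "or_discovery"):
    """Power-expected number of successful replications.

    Returns ``(expected, attempts_with_power)`` where ``expected`` is
    the sum of per-attempt powers (equivalently n * mean power).  An
    empty table yields 0.0.
    """
    if len(attempts) == 0:
        return 0.0, attempts.copy()
    if "power" in attempts.columns and attempts["power"].notna().all():
        out = attempts.copy()
    else:
        out = attach_power(attempts, alpha=alpha, direction=direction,
                           or_column=or_column)
    return float(out["power"].sum()), out
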