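"""Single-hit Poisson estimation of tumor-initiating-cell frequency.

In a limiting-dilution assay, decreasing cell doses are transplanted and
each mouse is scored tumor-positive or negative.  Under the single-hit
Poisson model a dose of ``d`` cells contains ``Poisson(theta * d)``
TICs and a tumor forms iff at least one is present:

    P(tumor | dose d) = 1 - exp(-theta * d)

``theta`` is the per-cell TIC rate; the frequency is reported as
"1 in round(1/theta)".  The maximum-likelihood fit, its 95% confidence
interval on the complementary log-log scale (the convention of standard
LDA software), and a one-degree-of-freedom likelihood-ratio comparison of
two groups are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LDATable",
    "TICFrequencyEstimate",
    "fit_single_hit",
    "compare_groups",
]

_LOG_THETA_BOUNDS = (-35.0, 10.0)


@dataclass(frozen=True)
class LDATable:
    """Dose-response table: cells injected, mice tested, mice tumor-positive."""

    doses: Tuple[float, ...]
    n_tested: Tuple[int, ...]
    n_positive: Tuple[int, ...]
    group: str = ""

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.n_tested) == len(self.n_positive) >= 1):
            raise ValueError("doses, n_tested, n_positive must align and be nonempty")
        for d, n, k in zip(self.doses, self.n_tested, self.n_positive):
            if d <= 0:
                raise ValueError(f"doses must be > 0, got {d}")
            if not (0 <= k <= n):
                raise ValueError(f"need 0 <= positive <= tested, got {k}/{n}")

    @classmethod
    def from_records(
        cls, rows: Sequence[Tuple[float, int, int]], group: str = ""
    ) -> "LDATable":
        d, n, k = zip(*rows)
        return cls(tuple(d), tuple(n), tuple(k), group=group)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str = "") -> "LDATable":
        return cls(
            tuple(df["dose"].astype(float)),
            tuple(df["tested"].astype(int)),
            tuple(df["positive"].astype(int)),
            group=group,
        )

    def arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.asarray(self.doses, dtype=float),
            np.asarray(self.n_tested, dtype=float),
            np.asarray(self.n_positive, dtype=float),
        )


@dataclass
class TICFrequencyEstimate:
    """Single-hit Poisson MLE of the per-cell TIC rate theta."""

    theta: float
    frequency_denominator: Optional[int]  # round(1/theta); None if theta == 0
    ci95_denominator: Tuple[float, float]
    loglik: float
    flags: List[str] = field(default_factory=list)


def _loglik(log_theta: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    theta = math.exp(log_theta)
    mu = theta * d
    with np.errstate(divide="ignore"):
        log_p = np.log(np.clip(-np.expm1(-mu), 1e-300, 1.0))
    return float(np.sum(k * log_p - (n - k) * mu))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fit_single_hit(table: LDATable) -> TICFrequencyEstimate:
    """Maximum-likelihood single-hit Poisson fit.

    The likelihood is maximized over ``log theta``; the 95% CI comes from
    the observed Fisher information on the log scale.  All-negative tables
    yield an infinite frequency denominator; all-positive tables a
    boundary estimate with a warning.
    """
    d, n, k = table.arrays()
    if k.sum() == 0:
        warnings.warn("no tumor-positive mouse: TIC frequency unbounded (theta -> 0)")
        return TICFrequencyEstimate(
            theta=0.0,
            frequency_denominator=None,
            ci95_denominator=(float("inf"), float("inf")),
            loglik=0.0,
            flags=["all_negative"],
        )
    flags: List[str] = []
    if np.all(k == n):
        # likelihood increases monotonically in theta: boundary estimate
        warnings.warn("every mouse tumor-positive: theta estimated at boundary")
        flags.append("all_positive_boundary")
        log_theta = _LOG_THETA_BOUNDS[1]
        return TICFrequencyEstimate(
            theta=math.exp(log_theta),
            frequency_denominator=_round_half_away(math.exp(-log_theta)),
            ci95_denominator=(0.0, float("inf")),
            loglik=_loglik(log_theta, d, n, k),
            flags=flags,
        )
    res = optimize.minimize_scalar(
        lambda lt: -_loglik(lt, d, n, k),
        bounds=_LOG_THETA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-12},
    )
    log_theta = float(res.x)
    theta = math.exp(log_theta)
    # expected Fisher information on the log-theta (cloglog) scale — the
    # convention of the standard LDA fitting tools:
    # I = sum n_i mu_i^2 exp(-mu_i) / (1 - exp(-mu_i)), mu_i = theta d_i
    mu = theta * d
    with np.errstate(divide="ignore", over="ignore"):
        denom_term = -np.expm1(-mu)
        info = float(
            np.sum(np.where(denom_term > 0, n * mu**2 * np.exp(-mu) / np.where(denom_term > 0, denom_term, 1.0), 0.0))
        )
    if info > 0:
        se = 1.0 / math.sqrt(info)
        lo_t, hi_t = math.exp(log_theta - 1.96 * se), math.exp(log_theta + 1.96 * se)
        ci = (1.0 / hi_t, 1.0 / lo_t)  # denominator scale: 1/theta
    else:
        flags.append("information_nonpositive")
        ci = (0.0, float("inf"))
    return TICFrequencyEstimate(
        theta=theta,
        frequency_denominator=_round_half_away(1.0 / theta),
        ci95_denominator=ci,
        loglik=_loglik(log_theta, d, n, k),
        flags=flags,
    )


def compare_groups(a: LDATable, b: LDATable) -> Tuple[float, float]:
    """Likelihood-ratio test of equal TIC frequency in two groups.

    Common-theta fit on the pooled rows against separate fits; the
    statistic is referred to a 1-df chi-square.  Returns ``(statistic, p)``.
    Boundary fits are flagged through the warnings of :func:`fit_single_hit`.
    """
    fit_a = fit_single_hit(a)
    fit_b = fit_single_hit(b)
    pooled = LDATable(
        a.doses + b.doses,
        a.n_tested + b.n_tested,
        a.n_positive + b.n_positive,
        group="pooled",
    )
    fit_c = fit_single_hit(pooled)
    lr = 2.0 * (fit_a.loglik + fit_b.loglik - fit_c.loglik)
    lr = max(0.0, lr)
    return lr, float(stats.chi2.sf(lr, df=1))
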