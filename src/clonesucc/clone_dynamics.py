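"""Core stochastic processes for clonal tracking of tumor-initiating cells.

A marked clone descends from a single engrafted founder cell and grows by a
Yule (linear pure-birth) process: every cell divides independently at a
constant rate ``lambda``.  After a growth period ``T`` the clone size,
started from one cell, is geometrically distributed on {1, 2, ...} with
success parameter ``q = exp(-lambda * T)``; only the product ``lambda * T``
is identifiable, and downstream inference is parameterized by ``q``.

On top of growth the module models the two thinning steps of the
experimental design: binomial engraftment of transplanted marked cells
(seeding) and binomial subsampling of the dissociated tumor for
integration-site analysis, followed by a relative-abundance detection
cutoff.  The composite per-clone detection probability is the ``p`` of the
binomial model ``K ~ B(n, p)`` used by the inference module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BirthProcessParams",
    "CloneState",
    "SamplingPlan",
    "yule_size_pmf",
    "yule_size_sample",
    "gillespie_yule",
    "seed_clones",
    "sample_tumor",
    "detection_probability",
]

#: default truncation tolerance for infinite-series summations
SERIES_TOL = 1e-12

#: guard against runaway event-by-event simulations, exp(lambda*T) above
#: this raises rather than looping for hours
GILLESPIE_EXPECTED_SIZE_GUARD = 1e8


@dataclass(frozen=True)
class BirthProcessParams:
    """Yule growth parameters: per-cell division rate and growth duration.

    Time units are arbitrary; only ``birth_rate * duration`` matters.
    """

    birth_rate: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.birth_rate >= 0):
            raise ValueError(f"birth_rate must be >= 0, got {self.birth_rate}")
        if not (self.duration >= 0):
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if not math.isfinite(self.duration):
            raise ValueError("duration must be finite")

    @property
    def q(self) -> float:
        """Geometric survival parameter ``exp(-lambda * T)`` in (0, 1]."""
        return math.exp(-self.birth_rate * self.duration)

    @classmethod
    def from_q(cls, q: float) -> "BirthProcessParams":
        """Build parameters with unit duration from the identifiable ``q``."""
        if not (0 < q <= 1):
            raise ValueError(f"q must lie in (0, 1], got {q}")
        return cls(birth_rate=-math.log(q), duration=1.0)

    @property
    def mean_size(self) -> float:
        """Expected clone size ``exp(lambda * T)`` after one growth period."""
        return math.exp(self.birth_rate * self.duration)


@dataclass
class CloneState:
    """One marked clone: identity, current cell count and proliferative state.

    ``active=False`` models a dormant tumor-initiating clone whose effective
    division rate is zero; ``birth_rate`` optionally overrides the shared
    rate for heterogeneous-rate alternatives.
    """

    clone_id: str
    size: int
    active: bool = True
    birth_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError(f"clone size must be >= 0, got {self.size}")


@dataclass(frozen=True)
class SamplingPlan:
    """How a dissociated tumor is assayed for integration sites.

    fraction_sampled
        Proportion ``f`` of tumor cells used for IS analysis (0 < f <= 1).
    read_depth
        Total sequence reads generated per sample.
    cutoff
        Minimum relative read abundance for a valid IS call (default 0.06%
        of total sequence counts).
    """

    fraction_sampled: float
    read_depth: int = 50_000
    cutoff: float = 0.0006

    def __post_init__(self) -> None:
        if not (0 < self.fraction_sampled <= 1):
            raise ValueError(
                f"fraction_sampled must lie in (0, 1], got {self.fraction_sampled}"
            )
        if self.read_depth <= 0:
            raise ValueError(f"read_depth must be > 0, got {self.read_depth}")
        if not (0 <= self.cutoff < 1):
            raise ValueError(f"cutoff must lie in [0, 1), got {self.cutoff}")


# ---------------------------------------------------------------------------
# Yule clone growth
# ---------------------------------------------------------------------------

def yule_size_pmf(k, params: BirthProcessParams):
    """P(clone size = k at time T | one founder at time 0).

    The size of a single-ancestor Yule clone is geometric on {1, 2, ...}:
    ``P(Z = k) = q (1 - q)**(k - 1)`` with ``q = exp(-lambda T)``.  Accepts
    scalar or array ``k``; mean is ``exp(lambda T)``.
    """
    k_arr = np.asarray(k)
    if not np.issubdtype(k_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(k_arr, 1), 0)):
            raise ValueError("clone size k must be a positive integer")
        k_arr = k_arr.astype(np.int64)
    if np.any(k_arr < 1):
        raise ValueError("clone size k must be >= 1")
    q = params.q
    out = stats.geom.pmf(k_arr, q)
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out


def yule_size_sample(
    params: BirthProcessParams, n_clones: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_clones`` i.i.d. Yule clone sizes (direct geometric sampler)."""
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if n_clones == 0:
        return np.empty(0, dtype=np.int64)
    return rng.geometric(params.q, size=n_clones).astype(np.int64)


def gillespie_yule(
    params: BirthProcessParams,
    rng: np.random.Generator,
    expected_size_guard: float = GILLESPIE_EXPECTED_SIZE_GUARD,
) -> int:
    """One exact event-by-event realization of the Yule process.

    Independent oracle for :func:`yule_size_sample`: waiting time to the
    next division at size ``n`` is exponential with rate ``lambda * n``.
    """
    lam, T = params.birth_rate, params.duration
    if params.mean_size > expected_size_guard:
        raise RuntimeError(
            f"expected clone size {params.mean_size:.3g} exceeds guard "
            f"{expected_size_guard:.3g}; runaway simulation"
        )
    if lam == 0 or T == 0:
        return 1
    size = 1
    t = rng.exponential(1.0 / (lam * size))
    while t < T:
        size += 1
        t += rng.exponential(1.0 / (lam * size))
    return size


# ---------------------------------------------------------------------------
# Seeding and tumor subsampling
# ---------------------------------------------------------------------------

def seed_clones(
    n_candidate_cells: int, seeding_prob: float, rng: np.random.Generator
) -> int:
    """Number of transplanted marked cells that engraft and found a clone.

    Engraftment is Bernoulli per cell with a common seeding probability, so
    the count is Binomial(n_candidate_cells, seeding_prob).
    """
    if not (0 <= seeding_prob <= 1):
        raise ValueError(f"seeding_prob must lie in [0, 1], got {seeding_prob}")
    if n_candidate_cells < 0:
        raise ValueError("n_candidate_cells must be >= 0")
    return int(rng.binomial(n_candidate_cells, seeding_prob))


def sample_tumor(
    clone_sizes: Sequence[int],
    plan: SamplingPlan,
    rng: np.random.Generator,
    strategy: str = "binomial",
) -> np.ndarray:
    """Cells per clone drawn into the IS-analysis aliquot.

    ``strategy="binomial"`` thins each clone independently (each cell kept
    with probability ``f``); ``strategy="hypergeometric"`` draws an exact
    aliquot of ``round(f * total)`` cells without replacement.  At tumor
    sizes far above the aliquot the two are indistinguishable.
    """
    sizes = np.asarray(clone_sizes, dtype=np.int64)
    if np.any(sizes < 0):
        raise ValueError("clone sizes must be >= 0")
    if strategy == "binomial":
        return rng.binomial(sizes, plan.fraction_sampled).astype(np.int64)
    if strategy == "hypergeometric":
        total = int(sizes.sum())
        n_draw = int(round(plan.fraction_sampled * total))
        return rng.multivariate_hypergeometric(sizes, n_draw).astype(np.int64)
    raise ValueError(f"unknown sampling strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Composite detection probability
# ---------------------------------------------------------------------------

def detection_probability(
    params: BirthProcessParams,
    plan: SamplingPlan,
    tumor_size: int,
    tol: float = SERIES_TOL,
    max_terms: int = 50_000_000,
) -> float:
    """Probability that one engrafted clone is called in the IS assay.

    Composite model: clone size ``Z`` is Yule-geometric with parameter
    ``q``; sampled cells ``S ~ Binomial(Z, f)``; the clone is called iff
    ``S >= 1`` and its expected read share — modeled as its sampled-cell
    share ``S / (f * tumor_size)`` — is at least the cutoff ``c``.  The
    detection condition is therefore ``S >= m`` with
    ``m = max(1, ceil(c * f * tumor_size))``.

    Computed as ``1 - sum_k P(Z=k) P(Binom(k, f) <= m - 1)`` with the series
    truncated once the remaining mass is provably below ``tol`` (the
    binomial CDF factor is nonincreasing in ``k``, so the geometric tail
    bounds the remainder).
    """
    if tumor_size < 1:
        raise ValueError("tumor_size must be >= 1")
    q, f, c = params.q, plan.fraction_sampled, plan.cutoff
    m = max(1, math.ceil(c * f * tumor_size - 1e-12))

    miss = 0.0  # P(not detected)
    k_start = 1
    chunk = 4096
    log1mq = math.log1p(-q) if q < 1 else -math.inf
    while True:
        k = np.arange(k_start, k_start + chunk, dtype=np.int64)
        pz = stats.geom.pmf(k, q)
        cdf = stats.binom.cdf(m - 1, k, f)
        miss += float(np.sum(pz * cdf))
        k_end = k_start + chunk - 1
        # remaining sum <= P(Z > k_end) * cdf(m-1; k_end, f)
        if q >= 1.0:
            break
        tail = math.exp(k_end * log1mq)
        if tail * cdf[-1] < tol or tail < tol:
            break
        k_start += chunk
        chunk = min(chunk * 2, 1_000_000)
        if k_start > max_terms:
            raise RuntimeError(
                f"detection_probability series did not reach tol={tol} "
                f"within {max_terms} terms"
            )
    return float(min(1.0, max(0.0, 1.0 - miss)))
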