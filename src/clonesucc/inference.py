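"""Clone-number bounds, seeding efficiencies and homogeneity tests.

The number of engrafted clones ``n`` in a tumor is never observed: only
``k`` clones are detected, and detection of each clone is (conditionally)
Bernoulli with probability ``p_det`` determined by the Yule growth
parameter ``q = exp(-lambda T)`` and the sampling fraction ``f`` — two
nuisance parameters that are themselves only known up to a confidence
rectangle.  All procedures here are built on the corresponding
confidence-interval construction:

* :func:`upper_bound_total_clones` inverts the exact binomial CDF of
  ``K ~ B(n, p_det(q, f))`` in ``n`` at every node of a grid over the
  nuisance rectangle and reports the supremum — a conservative upper
  confidence bound whose miscoverage is split (Bonferroni) between the
  rectangle and the binomial inversion;
* :func:`seeding_efficiency` converts the bound into a percentage of the
  initially transplanted marked cells;
* three hypothesis tests report *supremum p-values* over the nuisance grid
  (and over plausible reconstructions of the unobservable per-clone cell
  counts): equal proliferation rates within a tumor (H0,P1), constant
  growth rates across a transplantation step (H0,P2), and equal seeding
  efficiencies (H0,S).  Null distributions come from seeded parametric
  Monte Carlo at each grid node, so every p-value is reproducible
  bit-exactly for a fixed seed.

The identification of the two nuisance parameters with ``(q, f)`` and the
concrete test statistics are this package's own construction; see
``docs/methods.md``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .clone_dynamics import BirthProcessParams, SamplingPlan, detection_probability

__all__ = [
    "NuisanceRectangle",
    "CloneCountBound",
    "SeedingEfficiency",
    "TestResult",
    "CloneCountBoundCalculator",
    "upper_bound_total_clones",
    "seeding_efficiency",
    "test_equal_proliferation",
    "test_constant_growth",
    "test_equal_seeding",
]

N_UPPER_GUARD = 10**9


@dataclass(frozen=True)
class NuisanceRectangle:
    """Confidence rectangle for the nuisance pair ``(q, f)``.

    ``q`` is the Yule geometric parameter ``exp(-lambda T)``; ``f`` the
    effective sampling fraction.  ``coverage`` is the joint confidence of
    the rectangle (the caller constructs it; 0.995 pairs with a 0.005
    binomial inversion for a 99% overall bound).
    """

    q_interval: Tuple[float, float]
    f_interval: Tuple[float, float]
    coverage: float = 0.995

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("q", self.q_interval), ("f", self.f_interval)):
            if not (0 < lo <= hi <= 1):
                raise ValueError(
                    f"{name}_interval must satisfy 0 < lo <= hi <= 1, got ({lo}, {hi})"
                )
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must lie in (0, 1)")

    def grid(self, n_q: int, n_f: int) -> Tuple[np.ndarray, np.ndarray]:
        q = np.linspace(self.q_interval[0], self.q_interval[1], n_q)
        f = np.linspace(self.f_interval[0], self.f_interval[1], n_f)
        return q, f

    @property
    def center(self) -> Tuple[float, float]:
        return (
            0.5 * (self.q_interval[0] + self.q_interval[1]),
            0.5 * (self.f_interval[0] + self.f_interval[1]),
        )


@dataclass
class CloneCountBound:
    """Upper confidence bound on the number of engrafted clones."""

    k_observed: int
    n_upper: int
    confidence: float
    p_det_range: Tuple[float, float]
    grid_resolution: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_upper < self.k_observed:
            raise ValueError("n_upper must be >= k_observed")


@dataclass
class SeedingEfficiency:
    """Engraftment efficiency as percent of transplanted marked cells."""

    bound: CloneCountBound
    n_marked_transplanted: int
    efficiency_interval_pct: Tuple[float, float]


@dataclass
class TestResult:
    """Outcome of one nuisance-supremum hypothesis test."""

    hypothesis: str
    statistic: float
    p_supremum: float
    p_pointwise: Dict[Tuple[float, ...], float]
    grid_resolution: Tuple[int, ...]
    mc_replicates: int
    seed: int
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clone-number upper bound
# ---------------------------------------------------------------------------

def _invert_binomial_n(k: int, p: float, alpha: float) -> int:
    """Largest n with P(K <= k | n, p) >= alpha (exact CDF, bisection).

    The CDF is nonincreasing in n at fixed (k, p); at p = 1 the bound is k.
    """
    if p >= 1.0:
        return k
    if p <= 0.0:
        raise ValueError("p_det must be positive to bound n")
    lo = k  # cdf = 1 here
    hi = max(2 * k + 2, 8)
    while stats.binom.cdf(k, hi, p) >= alpha:
        lo = hi
        hi *= 2
        if hi > N_UPPER_GUARD:
            raise RuntimeError(
                f"n upper bound exceeds guard {N_UPPER_GUARD} (p_det={p:.3g})"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if stats.binom.cdf(k, mid, p) >= alpha:
            lo = mid
        else:
            hi = mid
    return lo


class CloneCountBoundCalculator:
    """Precomputes the detection-probability grid over a nuisance rectangle
    so that bounds for many observed counts reuse the same grid.

    The binomial inversion is antitone in ``p_det``, so the supremum of the
    bound over the grid is the bound at the grid minimum of ``p_det``
    (usually near the ``(q_max, f_min)`` corner; with a nonzero cutoff the
    read threshold scales with ``f`` and the minimum may sit off the
    corner, which is why the whole grid is evaluated).  A doubling
    refinement pass verifies that the grid resolves the extremum.
    """

    def __init__(
        self,
        rectangle: NuisanceRectangle,
        tumor_size: int,
        cutoff: float = 0.0006,
        confidence: float = 0.99,
        alpha_split: float = 0.5,
        grid_size: Tuple[int, int] = (25, 25),
        refine: bool = True,
    ) -> None:
        if not (0 < confidence < 1):
            raise ValueError("confidence must lie in (0, 1)")
        if not (0 < alpha_split < 1):
            raise ValueError("alpha_split must lie in (0, 1)")
        self.rectangle = rectangle
        self.tumor_size = tumor_size
        self.cutoff = cutoff
        self.confidence = confidence
        self.alpha_binomial = (1.0 - confidence) * alpha_split
        self.grid_size = grid_size
        needed = 1.0 - (1.0 - confidence) * (1.0 - alpha_split)
        if rectangle.coverage < needed - 1e-12:
            warnings.warn(
                f"rectangle coverage {rectangle.coverage} below the "
                f"{needed} required for a {confidence:.0%} overall bound",
                stacklevel=2,
            )
        self._pgrid = self._compute_grid(*grid_size)
        if refine:
            refined = self._compute_grid(2 * grid_size[0] - 1, 2 * grid_size[1] - 1)
            if abs(refined.min() - self._pgrid.min()) > 1e-3:
                raise RuntimeError(
                    "nuisance grid too coarse: p_det extremum moved by "
                    f"{abs(refined.min() - self._pgrid.min()):.2e} on refinement"
                )
            self._pgrid = refined
        self._cache: Dict[int, int] = {}

    def _compute_grid(self, n_q: int, n_f: int) -> np.ndarray:
        qs, fs = self.rectangle.grid(n_q, n_f)
        out = np.empty((n_q, n_f))
        for i, q in enumerate(qs):
            params = BirthProcessParams.from_q(q)
            for j, f in enumerate(fs):
                plan = SamplingPlan(fraction_sampled=f, cutoff=self.cutoff)
                out[i, j] = detection_probability(params, plan, self.tumor_size)
        return out

    @property
    def p_det_range(self) -> Tuple[float, float]:
        return float(self._pgrid.min()), float(self._pgrid.max())

    def bound(self, k_observed: int) -> CloneCountBound:
        if k_observed < 0:
            raise ValueError("k_observed must be >= 0")
        if k_observed not in self._cache:
            self._cache[k_observed] = _invert_binomial_n(
                k_observed, self._pgrid.min(), self.alpha_binomial
            )
        return CloneCountBound(
            k_observed=k_observed,
            n_upper=self._cache[k_observed],
            confidence=self.confidence,
            p_det_range=self.p_det_range,
            grid_resolution=self.grid_size,
        )


def upper_bound_total_clones(
    k_observed: int,
    rectangle: NuisanceRectangle,
    tumor_size: int,
    cutoff: float = 0.0006,
    confidence: float = 0.99,
    alpha_split: float = 0.5,
    grid_size: Tuple[int, int] = (25, 25),
    refine: bool = True,
) -> CloneCountBound:
    """Supremum upper confidence bound for the engrafted clone number.

    For each nuisance node the exact binomial CDF is inverted in ``n``;
    the reported bound is the supremum over the rectangle grid.  The total
    miscoverage ``1 - confidence`` is split Bonferroni-style between the
    rectangle and the binomial inversion (``alpha_split`` to the binomial).
    """
    calc = CloneCountBoundCalculator(
        rectangle,
        tumor_size,
        cutoff=cutoff,
        confidence=confidence,
        alpha_split=alpha_split,
        grid_size=grid_size,
        refine=refine,
    )
    return calc.bound(k_observed)


def seeding_efficiency(
    bound: CloneCountBound, n_marked_transplanted: int
) -> SeedingEfficiency:
    """Percent of transplanted marked cells that founded a clone:
    interval ``[k_observed, n_upper] / n_marked * 100``."""
    if n_marked_transplanted < bound.k_observed:
        raise ValueError(
            "n_marked_transplanted must be >= the number of observed clones"
        )
    lo = 100.0 * bound.k_observed / n_marked_transplanted
    hi = 100.0 * bound.n_upper / n_marked_transplanted
    return SeedingEfficiency(
        bound=bound,
        n_marked_transplanted=n_marked_transplanted,
        efficiency_interval_pct=(lo, hi),
    )


# ---------------------------------------------------------------------------
# shared helpers for the supremum tests
# ---------------------------------------------------------------------------

def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def shares_to_counts(shares: np.ndarray, scale: float) -> np.ndarray:
    """Reconstruct sampled-cell counts from read shares.

    Per-clone cell counts are unobservable; reads are a proxy.  Counts are
    ``round(share * scale)`` (half to even), floored at 1 for detected
    clones — part of the nuisance constellation the suprema range over.
    """
    return np.maximum(1, _round_half_even(np.asarray(shares, dtype=float) * scale))


def _mc_p_upper(null_stats: np.ndarray, observed: float) -> float:
    """Add-one Monte-Carlo p-value P(T* >= T_obs)."""
    return float((1 + np.sum(null_stats >= observed - 1e-12)) / (len(null_stats) + 1))


def _spawn_rngs(seed: int, n: int) -> List[np.random.Generator]:
    """Deterministic child generators: SeedSequence(seed).spawn(n)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _scale_grid(interval: Tuple[float, float], n: int) -> np.ndarray:
    lo, hi = interval
    if not (0 < lo <= hi):
        raise ValueError(f"scale interval must satisfy 0 < lo <= hi, got {interval}")
    grid = np.linspace(lo, hi, n)
    center = 0.5 * (lo + hi)
    if not np.any(np.isclose(grid, center)):
        grid = np.sort(np.append(grid, center))
    return grid


# ---------------------------------------------------------------------------
# H0,P1: equal proliferation rates within a tumor
# ---------------------------------------------------------------------------

def _geom_loglik_fitted(x: np.ndarray) -> float:
    """Maximized i.i.d.-geometric log likelihood (q_hat = 1/mean)."""
    n = x.size
    m = x.mean()
    qh = 1.0 / m
    extra = x.sum() - n
    return n * math.log(qh) + (extra * math.log1p(-qh) if extra > 0 else 0.0)


def _geom_loglik_saturated(x: np.ndarray) -> float:
    """Per-clone geometric log likelihood with q_i = 1/x_i."""
    x = x.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = -np.log(x) + (x - 1) * np.log1p(-1.0 / x)
    return float(np.where(x > 1, term, 0.0).sum())


def _llr_statistic(x: np.ndarray) -> float:
    return 2.0 * (_geom_loglik_saturated(x) - _geom_loglik_fitted(x))


def _llr_statistic_rows(x: np.ndarray) -> np.ndarray:
    """Vectorized `_llr_statistic` over rows of a (B, n) array."""
    xf = x.astype(float)
    n = x.shape[1]
    m = xf.mean(axis=1)
    extra = xf.sum(axis=1) - n
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_fit = n * np.log(1.0 / m) + np.where(
            extra > 0, extra * np.log1p(-1.0 / m), 0.0
        )
        sat_terms = np.where(xf > 1, -np.log(xf) + (xf - 1) * np.log1p(-1.0 / xf), 0.0)
    return 2.0 * (sat_terms.sum(axis=1) - ll_fit)


def test_equal_proliferation(
    shares: Sequence[float],
    rectangle: NuisanceRectangle,
    scale_interval: Tuple[float, float],
    mc_replicates: int = 2000,
    seed: int = 0,
    grid_size: Tuple[int, int] = (5, 5),
) -> TestResult:
    """H0,P1: all marked clones within a tumor divide at the same rate.

    Under the null the reconstructed sampled-cell counts of detected clones
    are i.i.d. Yule-geometric.  Statistic: log-likelihood ratio of the
    saturated per-clone geometric model against the common-``q`` fit.  At
    every grid node (``q`` from the rectangle, count scale from
    ``scale_interval``) the null distribution is generated by parametric
    bootstrap; the supremum p-value over nodes is reported.
    """
    shares = np.asarray(shares, dtype=float)
    if shares.size < 2:
        warnings.warn("fewer than 2 clones: no proliferation contrast, p = 1")
        return TestResult(
            hypothesis="H0,P1",
            statistic=float("nan"),
            p_supremum=1.0,
            p_pointwise={},
            grid_resolution=grid_size,
            mc_replicates=mc_replicates,
            seed=seed,
            flags=["fewer_than_two_clones"],
        )
    qs = _scale_grid(rectangle.q_interval, grid_size[0])
    scales = _scale_grid(scale_interval, grid_size[1])
    rngs = _spawn_rngs(seed, len(qs) * len(scales))
    pointwise: Dict[Tuple[float, ...], float] = {}
    stat_center = float("nan")
    center_q = 0.5 * sum(rectangle.q_interval)
    center_s = 0.5 * sum(scale_interval)
    node = 0
    for q in qs:
        for s in scales:
            x = shares_to_counts(shares, s)
            t_obs = _llr_statistic(x)
            draws = rngs[node].geometric(q, size=(mc_replicates, x.size))
            t_null = _llr_statistic_rows(draws)
            pointwise[(float(q), float(s))] = _mc_p_upper(t_null, t_obs)
            if math.isclose(q, center_q) and math.isclose(s, center_s):
                stat_center = t_obs
            node += 1
    return TestResult(
        hypothesis="H0,P1",
        statistic=stat_center,
        p_supremum=max(pointwise.values()),
        p_pointwise=pointwise,
        grid_resolution=grid_size,
        mc_replicates=mc_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# H0,P2: constant growth rates across a transplantation step
# ---------------------------------------------------------------------------

def _deviance(observed: np.ndarray, expected: np.ndarray) -> float:
    o = observed.astype(float)
    e = np.maximum(expected.astype(float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    return 2.0 * float(terms.sum())


def test_constant_growth(
    parent_shares: Sequence[float],
    daughter_shares: Sequence[float],
    transplant_fraction: float,
    rectangle: NuisanceRectangle,
    parent_cells_interval: Tuple[float, float],
    daughter_total_counts: int,
    mc_replicates: int = 2000,
    seed: int = 0,
    grid_size: Tuple[int, int] = (5, 5),
) -> TestResult:
    """H0,P2: clones grow at the same rate in parent and daughter tumors.

    ``parent_shares``/``daughter_shares`` are aligned per-clone read shares
    relative to each tumor's *total* reads (clones detected in the parent;
    a daughter share of 0 means not redetected).  Everything not among
    these clones — undetected parent clones and newly appearing daughter
    clones — forms an explicit "rest" category, so the vanishing of
    formerly dominant clones is visible to the statistic.

    Under the null each parent clone's daughter contribution derives from
    its parent cell count through binomial transplant thinning followed by
    common Yule growth; the statistic is the multinomial deviance between
    observed and propagated daughter counts.  Monte-Carlo null per grid
    node (``q`` and parent cell number nuisances); supremum p reported.
    """
    p_sh = np.asarray(parent_shares, dtype=float)
    d_sh = np.asarray(daughter_shares, dtype=float)
    if p_sh.shape != d_sh.shape:
        raise ValueError("parent and daughter share vectors must align")
    if not (0 < transplant_fraction <= 1):
        raise ValueError("transplant_fraction must lie in (0, 1]")
    if p_sh.size == 0 or not np.any(d_sh > 0):
        warnings.warn(
            "no clone detected in both tumors: growth test degenerates "
            "to seeding reporting"
        )
        return TestResult(
            hypothesis="H0,P2",
            statistic=float("nan"),
            p_supremum=1.0,
            p_pointwise={},
            grid_resolution=grid_size,
            mc_replicates=mc_replicates,
            seed=seed,
            flags=["no_shared_clones"],
        )
    rest_share = max(0.0, 1.0 - p_sh.sum())
    e_shares = np.append(p_sh, rest_share)
    e_counts = daughter_total_counts * e_shares / e_shares.sum()
    d_counts = _round_half_even(d_sh * daughter_total_counts)
    d_counts = np.append(d_counts, max(0, daughter_total_counts - d_counts.sum()))
    t_obs = _deviance(d_counts, e_counts)

    qs = _scale_grid(rectangle.q_interval, grid_size[0])
    n_parents = _scale_grid(parent_cells_interval, grid_size[1])
    rngs = _spawn_rngs(seed, len(qs) * len(n_parents))
    pointwise: Dict[Tuple[float, ...], float] = {}
    node = 0
    for q in qs:
        for n_p in n_parents:
            rng = rngs[node]
            cells = _round_half_even(e_shares * n_p)
            cells = np.maximum(cells, np.append(np.ones(p_sh.size, dtype=np.int64), 0))
            founders = rng.binomial(
                cells[None, :].repeat(mc_replicates, axis=0), transplant_fraction
            )
            grown = founders + np.where(
                founders > 0, rng.negative_binomial(np.maximum(founders, 1), q), 0
            )
            tot = grown.sum(axis=1)
            t_null = np.empty(mc_replicates)
            for b in range(mc_replicates):
                if tot[b] == 0:
                    t_null[b] = 0.0
                    continue
                w = grown[b] / tot[b]
                sim = rng.multinomial(daughter_total_counts, w)
                t_null[b] = _deviance(sim, e_counts)
            pointwise[(float(q), float(n_p))] = _mc_p_upper(t_null, t_obs)
            node += 1
    return TestResult(
        hypothesis="H0,P2",
        statistic=t_obs,
        p_supremum=max(pointwise.values()),
        p_pointwise=pointwise,
        grid_resolution=grid_size,
        mc_replicates=mc_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# H0,S: equal seeding efficiencies
# ---------------------------------------------------------------------------

def _fit_common_seeding_rate(sizes: np.ndarray, engrafted: np.ndarray) -> float:
    """MLE of the common per-cell seeding rate r with
    P(clone engrafts) = 1 - (1 - r)**size."""
    if engrafted.all():
        return 1.0
    if not engrafted.any():
        return 0.0

    def negll(logit_r: float) -> float:
        r = 1.0 / (1.0 + math.exp(-logit_r))
        g = 1.0 - r
        with np.errstate(divide="ignore"):
            p = -np.expm1(sizes * math.log(g)) if g > 0 else np.ones_like(sizes, float)
        p = np.clip(p, 1e-300, 1.0)
        ll = np.where(engrafted, np.log(p), sizes * math.log(max(g, 1e-300)))
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        negll, bounds=(-30.0, 30.0), method="bounded", options={"xatol": 1e-10}
    )
    return 1.0 / (1.0 + math.exp(-res.x))


def _conditional_engraftment_draws(
    probs: np.ndarray,
    k: int,
    n_draws: int,
    rng: np.random.Generator,
    max_batches: int = 400,
) -> Optional[np.ndarray]:
    """Draw engraftment label vectors with sum k from independent
    Bernoulli(probs), by rejection; None if acceptance is too poor."""
    n = probs.size
    out = []
    got = 0
    for _ in range(max_batches):
        batch = rng.random((max(256, n_draws), n)) < probs
        okay = batch[batch.sum(axis=1) == k]
        if okay.size:
            out.append(okay)
            got += okay.shape[0]
        if got >= n_draws:
            return np.concatenate(out, axis=0)[:n_draws]
    return None


def test_equal_seeding(
    transplanted_shares: Sequence[float],
    engrafted: Sequence[bool],
    scale_interval: Tuple[float, float],
    mc_replicates: int = 2000,
    seed: int = 0,
    grid_size: int = 5,
) -> TestResult:
    """H0,S: every transplanted cell has the same engraftment probability.

    Clone-level engraftment is then Bernoulli with
    ``p_i = 1 - (1 - r)**s_i`` where ``s_i`` is the clone's transplanted
    cell count (reconstructed from its read share over the
    ``scale_interval`` nuisance grid) and ``r`` the common per-cell rate.
    Test: condition on the number of engrafting clones and compare the
    observed size-weighted engraftment statistic ``T = sum_i e_i log s_i``
    with its conditional null distribution (weighted label permutations
    drawn by rejection); two-sided Monte-Carlo p, supremum over the grid.
    """
    shares = np.asarray(transplanted_shares, dtype=float)
    e_obs = np.asarray(engrafted, dtype=bool)
    if shares.shape != e_obs.shape:
        raise ValueError("transplanted_shares and engrafted must align")
    if shares.size < 2:
        warnings.warn("fewer than 2 clones: no seeding contrast, p = 1")
        return TestResult(
            hypothesis="H0,S",
            statistic=float("nan"),
            p_supremum=1.0,
            p_pointwise={},
            grid_resolution=(grid_size,),
            mc_replicates=mc_replicates,
            seed=seed,
            flags=["fewer_than_two_clones"],
        )
    k = int(e_obs.sum())
    scales = _scale_grid(scale_interval, grid_size)
    rngs = _spawn_rngs(seed, len(scales))
    pointwise: Dict[Tuple[float, ...], float] = {}
    flags: List[str] = []
    stat_center = float("nan")
    center_s = 0.5 * sum(scale_interval)
    for rng, s in zip(rngs, scales):
        sizes = shares_to_counts(shares, s)
        logs = np.log(sizes.astype(float))
        t_obs = float(logs[e_obs].sum())
        if math.isclose(s, center_s):
            stat_center = t_obs
        if k == 0 or k == shares.size:
            pointwise[(float(s),)] = 1.0  # conditional law is degenerate
            continue
        r_hat = _fit_common_seeding_rate(sizes, e_obs)
        probs = -np.expm1(sizes * math.log1p(-min(r_hat, 1 - 1e-12)))
        draws = _conditional_engraftment_draws(probs, k, mc_replicates, rng)
        if draws is None:
            flags.append(f"unconditional_fallback_scale_{s:g}")
            draws = rng.random((mc_replicates, shares.size)) < probs
        t_null = draws @ logs
        lo = (1 + np.sum(t_null <= t_obs + 1e-12)) / (len(t_null) + 1)
        hi = (1 + np.sum(t_null >= t_obs - 1e-12)) / (len(t_null) + 1)
        pointwise[(float(s),)] = float(min(1.0, 2.0 * min(lo, hi)))
    return TestResult(
        hypothesis="H0,S",
        statistic=stat_center,
        p_supremum=max(pointwise.values()),
        p_pointwise=pointwise,
        grid_resolution=(grid_size,),
        mc_replicates=mc_replicates,
        seed=seed,
        flags=flags,
    )
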