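"""Synthetic serial-xenotransplantation experiments with ground truth.

Generates complete clonal-tracking experiments — per-tumor IS read tables
plus the true clone sizes and activity states behind them — under competing
models of tumor-initiating-cell (TIC) organization:

``succession``
    TIC activity is transient: an active clone's TIC lineage is exhausted
    with probability ``p_inactivate`` per passage, while dormant engrafted
    clones are recruited with probability ``p_activate``.  Distinct clone
    sets drive successive generations.
``hierarchy``
    A fixed subset of clones (``ltic_fraction``) retains persistent
    self-renewal and drives every generation; all other clones never
    contribute.
``stochastic``
    Every engrafted clone is equally likely to be active in any generation,
    independent of history.

The cellular model distinguishes TIC-competent cells (engraft, may
proliferate) from non-tumorigenic progeny (bulk tumor mass that fails to
re-engraft on transplantation).  Active clones grow as a Yule process with
identical per-cell division rates; because all rates are equal, the joint
composition of a tumor grown to a harvest size N is an embedded Polya urn,
i.e. Dirichlet-multinomial with weights equal to the active founder counts.
The generator uses that exact representation by default
(``growth_mode="fixed_size"``) so that tumors are harvested at a realistic
size regardless of generation; a fixed-duration mode with per-clone
negative-binomial Yule growth is available as ``growth_mode="fixed_duration"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .clone_dynamics import BirthProcessParams, SamplingPlan, seed_clones

__all__ = [
    "SimulationConfig",
    "ExperimentRecord",
    "TumorState",
    "simulate_marking",
    "simulate_generation",
    "simulate_serial_experiment",
]

#: GRCh37 / hs37d5 chromosome lengths used for uniform IS placement
HS37D5_CHROM_LENGTHS: Dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

TOTAL_SIZE_GUARD = 1_000_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one serial-transplantation experiment.

    Defaults emulate the study design: ~10^5 cells transplanted at 60%
    transduction efficiency, three generations, 10% of each tumor sampled
    for IS analysis, 40% re-transplanted per daughter mouse, 0.06% read
    cutoff.  Activity-transition probabilities are this package's
    operationalization of transient TIC activity (no published rates
    exist); they are calibrated so that succession-scenario summary metrics
    fall in the reported bands (4-16 IS per primary tumor, ~78%
    generation-exclusive clones, ~49% detected once).
    """

    n_cells_transplanted: int = 100_000
    transduction_efficiency: float = 0.6
    seeding_prob: float = 0.005
    seeding_prob_serial: float = 1.0
    growth: BirthProcessParams = field(
        default_factory=lambda: BirthProcessParams(birth_rate=1.0, duration=12.0)
    )
    growth_mode: str = "fixed_size"  # or "fixed_duration"
    target_tumor_size: int = 2_000_000
    generations: int = 3
    mice_per_generation: int = 2
    fraction_retransplanted: float = 0.4
    plan: SamplingPlan = field(
        default_factory=lambda: SamplingPlan(fraction_sampled=0.1)
    )
    scenario: str = "succession"
    p_inactivate: float = 0.75
    p_activate: float = 0.04
    ltic_fraction: float = 0.04
    tic_refresh: Optional[int] = None
    enzyme_dropout: float = 0.1
    read_depth: int = 50_000
    patient: str = "P1"
    experiment: str = "E1"
    site: str = "s.c."
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "transduction_efficiency", "seeding_prob", "seeding_prob_serial",
            "fraction_retransplanted", "p_inactivate", "p_activate",
            "ltic_fraction", "enzyme_dropout",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mice_per_generation < 1:
            raise ValueError("mice_per_generation must be >= 1")
        if self.scenario not in ("succession", "hierarchy", "stochastic"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.growth_mode not in ("fixed_size", "fixed_duration"):
            raise ValueError(f"unknown growth_mode {self.growth_mode!r}")
        alloc = (
            self.plan.fraction_sampled
            + self.mice_per_generation * self.fraction_retransplanted
        )
        if alloc > 1 + 1e-12:
            raise ValueError(
                "fraction_sampled + mice_per_generation * fraction_retransplanted "
                f"= {alloc:.3f} exceeds 1; cells cannot be conserved"
            )

    @property
    def n_marked(self) -> int:
        return int(math.floor(self.n_cells_transplanted * self.transduction_efficiency))

    @property
    def effective_tic_refresh(self) -> int:
        """TIC-competent cells an active clone retains after its burst.

        Transient activity ("very limited or no self-renewal") leaves at
        most one TIC-competent cell per burst, so a persisting clone
        continues in at most one daughter tumor; persistent LT-TIC clones
        in the hierarchy scenario maintain a self-renewing reservoir and
        are re-transmitted to every daughter.
        """
        if self.tic_refresh is not None:
            return self.tic_refresh
        return 50 if self.scenario == "hierarchy" else 1


@dataclass
class TumorState:
    """One tumor: per-clone identity, size, TIC reservoir and activity."""

    clone_ids: List[Tuple[str, int, str]]
    sizes: np.ndarray       # total cells per clone (bulk + TIC-competent)
    tic_cells: np.ndarray   # TIC-competent cells per clone
    active: np.ndarray      # proliferated in THIS tumor
    is_ltic: np.ndarray     # persistent self-renewal flag (hierarchy)

    @property
    def total_cells(self) -> int:
        return int(self.sizes.sum())


@dataclass
class ExperimentRecord:
    """Full experiment: design table, IS read tables and ground truth."""

    design: pd.DataFrame
    is_tables: pd.DataFrame
    truth: Dict[str, dict]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# marking
# ---------------------------------------------------------------------------

def _draw_is_labels(n: int, rng: np.random.Generator) -> List[Tuple[str, int, str]]:
    """n unique (chromosome, 1-based position, strand) labels, uniform over
    hs37d5 chromosome lengths."""
    chroms = list(HS37D5_CHROM_LENGTHS)
    lengths = np.array([HS37D5_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    labels: set = set()
    out: List[Tuple[str, int, str]] = []
    while len(out) < n:
        todo = n - len(out)
        ci = rng.choice(len(chroms), size=todo, p=probs)
        pos = rng.integers(1, lengths[ci].astype(np.int64) + 1)
        strand = rng.choice(["+", "-"], size=todo)
        for c, p, s in zip(ci, pos, strand):
            lab = (chroms[c], int(p), str(s))
            if lab not in labels:
                labels.add(lab)
                out.append(lab)
    return out


def simulate_marking(
    config: SimulationConfig, rng: np.random.Generator
) -> List[Tuple[str, int, str]]:
    """Unique IS labels of the lentivirally marked founder cells.

    ``floor(n_cells_transplanted * transduction_efficiency)`` founders, each
    carrying a unique vector-genome junction inherited by all its progeny.
    """
    return _draw_is_labels(config.n_marked, rng)


# ---------------------------------------------------------------------------
# growth of one tumor
# ---------------------------------------------------------------------------

def _grow_active_clones(
    founders: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Final sizes of active clones started from ``founders`` TIC cells.

    fixed_size: exact Polya-urn composition of a Yule race with identical
    rates stopped when the tumor reaches ``target_tumor_size`` (Dirichlet-
    multinomial with weights = founder counts).
    fixed_duration: independent per-clone Yule growth for duration T
    (sum of founder-many geometric sizes, i.e. shifted negative binomial).
    """
    if founders.size == 0:
        return founders.copy()
    if config.growth_mode == "fixed_duration":
        q = config.growth.q
        extra = rng.negative_binomial(founders, q)
        sizes = founders + extra
    else:
        n_add = max(0, int(config.target_tumor_size) - int(founders.sum()))
        gammas = rng.gamma(shape=founders.astype(float))
        w = gammas / gammas.sum()
        sizes = founders + rng.multinomial(n_add, w)
    if sizes.sum() > TOTAL_SIZE_GUARD:
        raise RuntimeError(
            f"total tumor size {sizes.sum():.3g} exceeds guard {TOTAL_SIZE_GUARD:.3g}"
        )
    return sizes.astype(np.int64)


def _update_activity(
    prev_active: np.ndarray,
    is_ltic: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scenario-specific activity transitions for clones in an inoculum.

    Succession: clones whose TIC lineage survived the previous burst (the
    exhaustion draw happens once, in the parent tumor at harvest) continue;
    dormant clones are recruited with ``p_activate``.
    """
    n = prev_active.size
    u = rng.random(n)
    if config.scenario == "succession":
        recruit = ~prev_active & (u < config.p_activate)
        return prev_active | recruit
    if config.scenario == "hierarchy":
        return is_ltic.copy()
    # stochastic: memoryless equal chance each generation
    return u < config.p_activate


def simulate_generation(
    inoculum: TumorState,
    config: SimulationConfig,
    rng: np.random.Generator,
    seeding_prob: Optional[float] = None,
) -> TumorState:
    """Grow one tumor from a transplanted inoculum.

    Per clone the TIC-competent cells engraft binomially (non-tumorigenic
    bulk fails to re-engraft); scenario rules update activity; active
    clones proliferate, dormant clones persist as quiescent TIC cells.
    After growth an active clone's TIC reservoir is refreshed to
    ``tic_refresh`` cells (self-renewal within the burst), so that clone
    persistence across passages is governed by the scenario transitions
    rather than by sampling noise on a single cell.
    """
    if len(inoculum.clone_ids) == 0:
        raise ValueError("inoculum must contain at least one clone")
    p_seed = config.seeding_prob_serial if seeding_prob is None else seeding_prob
    engrafted = np.array(
        [seed_clones(int(t), p_seed, rng) for t in inoculum.tic_cells],
        dtype=np.int64,
    )
    keep = engrafted > 0
    ids = [cid for cid, k in zip(inoculum.clone_ids, keep) if k]
    engrafted = engrafted[keep]
    prev_active = inoculum.active[keep]
    is_ltic = inoculum.is_ltic[keep]
    active = _update_activity(prev_active, is_ltic, config, rng)

    sizes = engrafted.copy()
    tic = engrafted.copy()
    if active.any():
        grown = _grow_active_clones(engrafted[active], config, rng)
        sizes[active] = grown
        tic[active] = np.minimum(config.effective_tic_refresh, grown)
    if config.scenario == "succession" and active.any():
        # proliferative exhaustion is decided once per burst, at harvest:
        # an exhausted clone's progeny carry no TIC-competent cells, so no
        # daughter tumor can redetect it (cf. dominant-clone persistence
        # approx. 1 - p_inactivate per transplantation step)
        exhausted = active & (rng.random(active.size) < config.p_inactivate)
        tic[exhausted] = 0
    return TumorState(
        clone_ids=ids, sizes=sizes, tic_cells=tic, active=active, is_ltic=is_ltic
    )


# ---------------------------------------------------------------------------
# assay and transplantation of one tumor
# ---------------------------------------------------------------------------

def _allocate_cells(
    tumor: TumorState, config: SimulationConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, List[np.ndarray], np.ndarray]:
    """Partition every clone's cells into (IS aliquot, per-daughter inocula,
    remainder) by a per-clone multinomial; cells are conserved exactly."""
    f = config.plan.fraction_sampled
    r = config.fraction_retransplanted
    m = config.mice_per_generation
    probs = [f] + [r] * m + [max(0.0, 1.0 - f - m * r)]
    probs = np.array(probs) / np.sum(probs)  # tolerate rounding at f+m*r==1
    counts = np.array(
        [rng.multinomial(int(s), probs) for s in tumor.sizes], dtype=np.int64
    )
    sampled = counts[:, 0]
    daughters = [counts[:, 1 + j] for j in range(m)]
    remainder = counts[:, -1]
    return sampled, daughters, remainder


def _tic_allocation(
    tumor: TumorState,
    sampled: np.ndarray,
    daughters: List[np.ndarray],
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """TIC-competent cells follow their clone's cell allocation
    hypergeometrically (TIC cells are exchangeable within a clone)."""
    out = []
    for j, d in enumerate(daughters):
        tic_d = np.array(
            [
                rng.hypergeometric(int(t), max(int(s) - int(t), 0), int(c))
                if s > 0 and t > 0 and c > 0 else 0
                for t, s, c in zip(tumor.tic_cells, tumor.sizes, d)
            ],
            dtype=np.int64,
        )
        out.append(tic_d)
    return out


def _make_read_tables(
    tumor_id: str,
    tumor: TumorState,
    sampled: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two enzyme-replicate read tables by multinomial allocation of
    ``read_depth`` reads over the sampled clones, with independent
    per-replicate IS dropout."""
    rows = []
    present = sampled > 0
    for enzyme in ("TSP509I", "MSEI"):
        keep = present & (rng.random(len(sampled)) >= config.enzyme_dropout)
        idx = np.where(keep)[0]
        if idx.size == 0:
            continue
        w = sampled[idx] / sampled[idx].sum()
        reads = rng.multinomial(config.read_depth, w)
        for i, nr in zip(idx, reads):
            if nr > 0:
                c, p, s = tumor.clone_ids[i]
                rows.append((c, p, s, tumor_id, enzyme, int(nr)))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "tumor_id", "enzyme", "reads"]
    )


# ---------------------------------------------------------------------------
# whole experiment
# ---------------------------------------------------------------------------

def simulate_serial_experiment(config: SimulationConfig) -> ExperimentRecord:
    """Full 1-degree -> 2-degree -> 3-degree experiment under one seed.

    The primary tumor is founded by the marked cells that engraft
    (``Binomial(n_marked, seeding_prob)``); IS labels are drawn for the
    engrafted founders only, which is distributionally identical to marking
    every founder and thinning (binomial thinning of i.i.d. uniform labels).
    Each tumor is assayed (two enzyme replicates) and split into
    ``mice_per_generation`` daughter inocula.
    """
    rng = np.random.default_rng(config.seed)
    n_engrafted = seed_clones(config.n_marked, config.seeding_prob, rng)
    if n_engrafted == 0:
        raise RuntimeError(
            "no marked cell engrafted; raise seeding_prob or cell numbers"
        )
    labels = _draw_is_labels(n_engrafted, rng)
    is_ltic = rng.random(n_engrafted) < config.ltic_fraction
    founders = TumorState(
        clone_ids=labels,
        sizes=np.ones(n_engrafted, dtype=np.int64),
        tic_cells=np.ones(n_engrafted, dtype=np.int64),
        active=np.zeros(n_engrafted, dtype=bool),
        is_ltic=is_ltic,
    )

    design_rows = []
    tables = []
    truth: Dict[str, dict] = {}

    def tumor_id(gen: int, index: int) -> str:
        return f"{config.patient}-{config.experiment}-G{gen}M{index}"

    # queue of (generation, mouse index counter per generation)
    counters = {g: 0 for g in range(1, config.generations + 1)}

    def process(
        inoculum: TumorState, gen: int, parent: Optional[str], n_injected: int,
        first_generation: bool,
    ) -> None:
        counters[gen] += 1
        tid = tumor_id(gen, counters[gen])
        p_seed = 1.0 if first_generation else None  # founders already engrafted
        tumor = simulate_generation(
            inoculum, config, rng, seeding_prob=p_seed
        )
        sampled, daughters, remainder = _allocate_cells(tumor, config, rng)
        tic_daughters = _tic_allocation(tumor, sampled, daughters, rng)
        tables.append(_make_read_tables(tid, tumor, sampled, config, rng))
        design_rows.append(
            {
                "tumor_id": tid,
                "patient": config.patient,
                "experiment": config.experiment,
                "generation": gen,
                "parent": parent,
                "site": config.site,
                "n_cells_injected": n_injected,
                "transduction_efficiency": config.transduction_efficiency,
                "fraction_sampled_for_is": config.plan.fraction_sampled,
                "fraction_retransplanted": config.fraction_retransplanted,
            }
        )
        truth[tid] = {
            "clone_sizes": dict(zip(tumor.clone_ids, tumor.sizes.tolist())),
            "active": dict(zip(tumor.clone_ids, tumor.active.tolist())),
            "n_engrafted_clones": len(tumor.clone_ids),
            "total_cells": tumor.total_cells,
            "cells_sampled": int(sampled.sum()),
            "cells_retransplanted": int(sum(int(d.sum()) for d in daughters)),
            "cells_remainder": int(remainder.sum()),
        }
        if gen < config.generations:
            for d, tic_d in zip(daughters, tic_daughters):
                keep = d > 0
                child = TumorState(
                    clone_ids=[c for c, k in zip(tumor.clone_ids, keep) if k],
                    sizes=d[keep],
                    tic_cells=tic_d[keep],
                    active=tumor.active[keep],
                    is_ltic=tumor.is_ltic[keep],
                )
                if len(child.clone_ids) == 0:
                    continue
                process(child, gen + 1, tid, int(d.sum()), first_generation=False)

    process(
        founders, 1, None, config.n_cells_transplanted, first_generation=True
    )

    design = pd.DataFrame(design_rows).set_index("tumor_id", drop=False)
    is_tables = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["chrom", "pos", "strand", "tumor_id", "enzyme", "reads"])
    )
    return ExperimentRecord(design=design, is_tables=is_tables, truth=truth, config=config)
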