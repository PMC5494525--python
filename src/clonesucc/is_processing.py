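"""Filtering of lentiviral integration-site (IS) read tables.

Raw LAM-PCR sequencing yields, per tumor, read counts for every detected
vector-genome junction, produced twice with different restriction enzymes
(TSP509I, MSEI) to enlarge genomic coverage.  This module turns those raw
per-replicate tables into validated per-tumor contribution matrices:

1. :func:`merge_enzyme_replicates` — union over enzymes, counts summed;
2. :func:`apply_abundance_cutoff` — drop IS below a minimal relative
   abundance (default 0.06% of a tumor's total sequence counts);
3. :func:`remove_collisions` — drop below-cutoff occurrences of IS seen in
   more than one independent experiment lineage (cross-contamination);
4. :func:`build_contribution_matrix` — renormalized IS x tumor matrix.

The pipeline order merge -> cutoff -> collisions -> matrix is part of the
contract: thresholding per-replicate instead of post-merge changes results.

Tables are pandas DataFrames with columns
``chrom, pos, strand, tumor_id, enzyme, reads`` (the TSV dialect of
:mod:`clonesucc.cli_io`); an IS is identified by the exact
``(chrom, pos, strand)`` triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IS_KEY",
    "ISReadRecord",
    "ContributionMatrix",
    "merge_enzyme_replicates",
    "apply_abundance_cutoff",
    "remove_collisions",
    "build_contribution_matrix",
    "run_filter_pipeline",
]

#: columns identifying one integration site
IS_KEY = ["chrom", "pos", "strand"]

VALID_ENZYMES = ("TSP509I", "MSEI")


@dataclass(frozen=True)
class ISReadRecord:
    """One IS observation in one tumor and one enzyme replicate."""

    chrom: str
    pos: int
    strand: str
    tumor_id: str
    enzyme: str
    reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.reads < 0:
            raise ValueError(f"reads must be >= 0, got {self.reads}")


def records_to_frame(records: Sequence[ISReadRecord]) -> pd.DataFrame:
    cols = ["chrom", "pos", "strand", "tumor_id", "enzyme", "reads"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols).astype(
            {"pos": np.int64, "reads": np.int64}
        )
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"IS table is missing columns: {missing}")


def merge_enzyme_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Union of the two enzyme replicates per (IS, tumor); counts summed.

    Raises on duplicate ``(IS, tumor, enzyme)`` rows — the input would be
    ambiguous.  Output columns: IS key, tumor_id, reads.
    """
    _require_columns(records, IS_KEY + ["tumor_id", "enzyme", "reads"])
    if len(records) == 0:
        return records[IS_KEY + ["tumor_id", "reads"]].copy()
    dup = records.duplicated(subset=IS_KEY + ["tumor_id", "enzyme"], keep=False)
    if dup.any():
        bad = records.loc[dup, IS_KEY + ["tumor_id", "enzyme"]].head()
        raise ValueError(
            f"duplicate (IS, tumor, enzyme) rows in input, e.g.\n{bad}"
        )
    merged = (
        records.groupby(IS_KEY + ["tumor_id"], as_index=False, sort=False)["reads"]
        .sum()
    )
    return merged


def per_tumor_totals(merged: pd.DataFrame) -> pd.Series:
    """Total merged read counts per tumor."""
    return merged.groupby("tumor_id")["reads"].sum()


def apply_abundance_cutoff(
    merged: pd.DataFrame, cutoff: float = 0.0006
) -> pd.DataFrame:
    """Remove IS whose read share within a tumor falls below ``cutoff``.

    Shares are computed against the tumor's *pre-filter* total, so the
    operation is idempotent only together with the totals it used; applied
    twice with recomputed totals it is still idempotent because surviving
    shares can only grow.
    """
    if not (0 < cutoff < 1):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    if len(merged) == 0:
        return merged.copy()
    totals = per_tumor_totals(merged)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"tumors with zero total reads: {bad}")
    share = merged["reads"] / merged["tumor_id"].map(totals)
    return merged.loc[share >= cutoff].reset_index(drop=True)


def remove_collisions(
    counts: pd.DataFrame,
    grouping: Mapping[str, str],
    cutoff: float = 0.0006,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Remove below-cutoff occurrences of IS shared across lineages.

    A *collision* is the same genomic IS coordinate observed in more than
    one independent experiment lineage — the signature of inter-sample
    contamination, since independent transductions virtually never hit the
    same base pair.  Only its occurrences whose read share is below
    ``cutoff`` are removed; at-or-above-cutoff occurrences are the
    biological signal of their own lineage and always retained.

    ``grouping`` maps every tumor_id to its lineage; ``totals`` optionally
    supplies pre-filter per-tumor totals (defaults to totals of ``counts``).
    """
    _require_columns(counts, IS_KEY + ["tumor_id", "reads"])
    if len(counts) == 0:
        return counts.copy()
    unmapped = set(counts["tumor_id"]) - set(grouping)
    if unmapped:
        raise ValueError(f"tumors without a lineage mapping: {sorted(unmapped)}")
    if totals is None:
        totals = per_tumor_totals(counts)
    lineage = counts["tumor_id"].map(dict(grouping))
    n_lineages = (
        lineage.groupby([counts[c] for c in IS_KEY]).transform("nunique")
    )
    share = counts["reads"] / counts["tumor_id"].map(totals)
    drop = (n_lineages > 1) & (share < cutoff)
    return counts.loc[~drop].reset_index(drop=True)


@dataclass
class ContributionMatrix:
    """IS x tumor matrix of relative read contributions plus detection flags.

    Rows (IS) are ordered by genomic coordinate, columns (tumors) by the
    order given at construction.  Per tumor, contributions over detected IS
    sum to 1 (tumors with no surviving IS are retained as all-undetected
    columns and listed in ``empty_tumors``).
    """

    is_ids: List[tuple]
    tumor_ids: List[str]
    contribution: np.ndarray
    detected: np.ndarray
    empty_tumors: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.contribution,
            index=pd.MultiIndex.from_tuples(self.is_ids, names=IS_KEY),
            columns=self.tumor_ids,
        )

    def detected_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.detected,
            index=pd.MultiIndex.from_tuples(self.is_ids, names=IS_KEY),
            columns=self.tumor_ids,
        )


def _chrom_sort_key(chrom: str):
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def build_contribution_matrix(
    cleaned: pd.DataFrame, tumor_order: Sequence[str] | None = None
) -> ContributionMatrix:
    """Per-tumor renormalized contribution matrix over surviving IS."""
    _require_columns(cleaned, IS_KEY + ["tumor_id", "reads"])
    if tumor_order is None:
        tumor_order = list(dict.fromkeys(cleaned["tumor_id"]))
    tumor_order = list(tumor_order)
    is_ids = sorted(
        {tuple(row) for row in cleaned[IS_KEY].itertuples(index=False)},
        key=lambda t: (_chrom_sort_key(t[0]), t[1], t[2]),
    )
    if len(is_ids) == 0 and len(tumor_order) == 0:
        raise ValueError("cannot build a contribution matrix from an empty table")
    is_index = {isid: i for i, isid in enumerate(is_ids)}
    tumor_index = {t: j for j, t in enumerate(tumor_order)}
    reads = np.zeros((len(is_ids), len(tumor_order)))
    for row in cleaned.itertuples(index=False):
        isid = (row.chrom, row.pos, row.strand)
        if row.tumor_id not in tumor_index:
            continue
        reads[is_index[isid], tumor_index[row.tumor_id]] += row.reads
    col_tot = reads.sum(axis=0)
    empty = [t for t, j in tumor_index.items() if col_tot[j] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        contribution = np.where(col_tot > 0, reads / np.where(col_tot > 0, col_tot, 1), 0.0)
    detected = reads > 0
    return ContributionMatrix(
        is_ids=is_ids,
        tumor_ids=tumor_order,
        contribution=contribution,
        detected=detected,
        empty_tumors=empty,
    )


def run_filter_pipeline(
    records: pd.DataFrame,
    grouping: Mapping[str, str],
    cutoff: float = 0.0006,
    tumor_order: Sequence[str] | None = None,
) -> ContributionMatrix:
    """Fixed-order pipeline: merge -> cutoff -> collisions -> matrix."""
    merged = merge_enzyme_replicates(records)
    totals = per_tumor_totals(merged)
    filtered = apply_abundance_cutoff(merged, cutoff=cutoff)
    cleaned = remove_collisions(filtered, grouping, cutoff=cutoff, totals=totals)
    return build_contribution_matrix(cleaned, tumor_order=tumor_order)
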