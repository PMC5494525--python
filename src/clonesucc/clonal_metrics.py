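"""Succession statistics over an IS x tumor contribution matrix.

Quantifies whether serial xenograft growth looks like *clonal succession*
(distinct, transiently active clone sets per generation) or a *fixed
hierarchy* (the same self-renewing clones active throughout):

- IS counts overall / per patient / per tumor;
- fraction of IS detected exclusively in a single generation;
- fraction of IS detected exactly once (overall and per generation);
- fraction of dominant clones (>= 50% of a tumor's reads) never seen in
  another generation;
- fraction of serial-tumor IS already present in the primary tumor;
- pairwise Jaccard overlap of sibling tumors transplanted from one donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .is_processing import ContributionMatrix

__all__ = [
    "GenerationAnnotation",
    "SuccessionSummary",
    "is_counts",
    "generation_exclusive_fraction",
    "detected_once_fraction",
    "dominant_nonpersistent_fraction",
    "prior_generation_fraction",
    "pairwise_overlap",
    "summarize",
]


@dataclass(frozen=True)
class GenerationAnnotation:
    """Per-tumor metadata: patient, experiment, generation, parent tumor.

    Generations are 1 (primary), 2 (secondary), 3 (tertiary); a parent's
    generation must be one less than its child's, and roots are generation 1.
    """

    table: pd.DataFrame  # index: tumor_id; columns: patient, experiment, generation, parent

    def __post_init__(self) -> None:
        required = {"patient", "experiment", "generation", "parent"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation is missing columns: {sorted(missing)}")
        for tumor_id, row in self.table.iterrows():
            parent = row["parent"]
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                if row["generation"] != 1:
                    raise ValueError(
                        f"tumor {tumor_id} has no parent but generation "
                        f"{row['generation']} (roots must be generation 1)"
                    )
            else:
                if parent not in self.table.index:
                    raise ValueError(f"unknown parent tumor {parent!r} of {tumor_id}")
                if self.table.loc[parent, "generation"] != row["generation"] - 1:
                    raise ValueError(
                        f"generation of {tumor_id} is not parent's + 1"
                    )

    def generation(self, tumor_id: str) -> int:
        return int(self.table.loc[tumor_id, "generation"])

    def check_covers(self, tumor_ids) -> None:
        missing = set(tumor_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"tumors without annotation: {sorted(missing)}")


@dataclass
class SuccessionSummary:
    """Container for all succession statistics of one analysis."""

    total_is: int
    is_per_tumor: Dict[str, int]
    is_per_patient: Dict[str, int]
    generation_exclusive_fraction: Optional[float]
    detected_once_fraction: Optional[float]
    detected_once_by_generation: Dict[int, Optional[float]]
    dominant_nonpersistent_fraction: Optional[float]
    prior_generation_fraction: Dict[str, Optional[float]]
    pairwise_overlap: Dict[Tuple[str, str], float]

    def to_dict(self) -> dict:
        return {
            "total_is": self.total_is,
            "is_per_tumor": self.is_per_tumor,
            "is_per_patient": self.is_per_patient,
            "generation_exclusive_fraction": self.generation_exclusive_fraction,
            "detected_once_fraction": self.detected_once_fraction,
            "detected_once_by_generation": {
                str(g): v for g, v in self.detected_once_by_generation.items()
            },
            "dominant_nonpersistent_fraction": self.dominant_nonpersistent_fraction,
            "prior_generation_fraction": self.prior_generation_fraction,
            "pairwise_overlap": {
                f"{a}|{b}": v for (a, b), v in self.pairwise_overlap.items()
            },
        }


def _detections(matrix: ContributionMatrix) -> pd.DataFrame:
    """Boolean IS x tumor detection frame."""
    return matrix.detected_frame()


def is_counts(
    matrix: ContributionMatrix, annotation: GenerationAnnotation
) -> Tuple[int, Dict[str, int], Dict[str, int]]:
    """Distinct-IS counts overall, per tumor and per patient."""
    annotation.check_covers(matrix.tumor_ids)
    det = _detections(matrix)
    any_det = det.any(axis=1)
    total = int(any_det.sum())
    per_tumor = {t: int(det[t].sum()) for t in matrix.tumor_ids}
    per_patient: Dict[str, int] = {}
    patients = annotation.table.loc[matrix.tumor_ids, "patient"]
    for patient in sorted(patients.unique()):
        cols = [t for t in matrix.tumor_ids if patients[t] == patient]
        per_patient[patient] = int(det[cols].any(axis=1).sum())
    return total, per_tumor, per_patient


def _generations_per_is(matrix: ContributionMatrix, annotation: GenerationAnnotation):
    det = _detections(matrix)
    gens = np.array([annotation.generation(t) for t in matrix.tumor_ids])
    return det, gens


def generation_exclusive_fraction(
    matrix: ContributionMatrix, annotation: GenerationAnnotation
) -> Optional[float]:
    """Fraction of IS detected in tumors of a single generation only."""
    annotation.check_covers(matrix.tumor_ids)
    det, gens = _generations_per_is(matrix, annotation)
    mask = det.to_numpy()
    n_is_detected = mask.any(axis=1).sum()
    if n_is_detected == 0:
        return None
    n_gens = np.array(
        [len(set(gens[row])) for row in mask if row.any()]
    )
    return float((n_gens == 1).sum() / n_is_detected)


def detected_once_fraction(
    matrix: ContributionMatrix, annotation: GenerationAnnotation
) -> Tuple[Optional[float], Dict[int, Optional[float]]]:
    """Fraction of IS detected in exactly one tumor, overall and per generation.

    Per generation g: among IS detected in generation-g tumors, the fraction
    whose only detection anywhere is that single generation-g tumor.
    """
    annotation.check_covers(matrix.tumor_ids)
    det, gens = _generations_per_is(matrix, annotation)
    mask = det.to_numpy()
    n_tumors_per_is = mask.sum(axis=1)
    detected = n_tumors_per_is > 0
    overall = float((n_tumors_per_is == 1).sum() / detected.sum()) if detected.any() else None
    per_gen: Dict[int, Optional[float]] = {}
    for g in sorted(set(gens)):
        in_g = mask[:, gens == g].any(axis=1)
        denom = int(in_g.sum())
        if denom == 0:
            per_gen[int(g)] = None
            continue
        once_here = in_g & (n_tumors_per_is == 1)
        per_gen[int(g)] = float(once_here.sum() / denom)
    return overall, per_gen


def dominant_nonpersistent_fraction(
    matrix: ContributionMatrix,
    annotation: GenerationAnnotation,
    dominance: float = 0.5,
) -> Optional[float]:
    """Among clones reaching >= ``dominance`` of a tumor's reads, the fraction
    never detected outside the generation(s) in which they were dominant."""
    if not (0 < dominance <= 1):
        raise ValueError(f"dominance must lie in (0, 1], got {dominance}")
    annotation.check_covers(matrix.tumor_ids)
    det, gens = _generations_per_is(matrix, annotation)
    mask = det.to_numpy()
    contrib = matrix.contribution
    dominant_rows = np.where((contrib >= dominance).any(axis=1))[0]
    if len(dominant_rows) == 0:
        return None
    nonpersistent = 0
    for i in dominant_rows:
        det_gens = set(gens[mask[i]])
        if len(det_gens) == 1:
            nonpersistent += 1
    return float(nonpersistent / len(dominant_rows))


def prior_generation_fraction(
    matrix: ContributionMatrix, annotation: GenerationAnnotation
) -> Dict[str, Optional[float]]:
    """Per experiment: fraction of serial-tumor (2/3 degree) IS already
    detected in that experiment's primary tumor(s).

    Experiments without serial tumors are reported as missing (None).
    """
    annotation.check_covers(matrix.tumor_ids)
    det = _detections(matrix)
    ann = annotation.table.loc[matrix.tumor_ids]
    result: Dict[str, Optional[float]] = {}
    for exp in sorted(ann["experiment"].unique()):
        cols = ann.index[ann["experiment"] == exp]
        primary = [t for t in cols if ann.loc[t, "generation"] == 1]
        serial = [t for t in cols if ann.loc[t, "generation"] > 1]
        if not serial:
            result[exp] = None
            continue
        serial_is = det[serial].any(axis=1)
        denom = int(serial_is.sum())
        if denom == 0:
            result[exp] = None
            continue
        primary_is = det[primary].any(axis=1) if primary else pd.Series(False, index=det.index)
        result[exp] = float((serial_is & primary_is).sum() / denom)
    return result


def pairwise_overlap(
    matrix: ContributionMatrix,
    annotation: GenerationAnnotation,
    denominator: str = "union",
) -> Dict[Tuple[str, str], float]:
    """Shared-IS fraction for every pair of sibling tumors (same donor tumor).

    ``denominator="union"`` gives the Jaccard index |A & B| / |A | B|;
    ``denominator="smaller"`` divides by the smaller detected set instead.
    """
    if denominator not in ("union", "smaller"):
        raise ValueError("denominator must be 'union' or 'smaller'")
    annotation.check_covers(matrix.tumor_ids)
    det = _detections(matrix)
    ann = annotation.table.loc[matrix.tumor_ids]
    result: Dict[Tuple[str, str], float] = {}
    parents = ann["parent"].fillna("__root__")
    for parent in parents.unique():
        sibs = sorted(ann.index[parents == parent])
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                a, b = sibs[i], sibs[j]
                sa, sb = det[a], det[b]
                inter = int((sa & sb).sum())
                if denominator == "union":
                    denom = int((sa | sb).sum())
                else:
                    denom = min(int(sa.sum()), int(sb.sum()))
                result[(a, b)] = float(inter / denom) if denom > 0 else 0.0
    return result


def summarize(
    matrix: ContributionMatrix,
    annotation: GenerationAnnotation,
    dominance: float = 0.5,
    overlap_denominator: str = "union",
) -> SuccessionSummary:
    """Compute every succession statistic in one pass."""
    total, per_tumor, per_patient = is_counts(matrix, annotation)
    once_overall, once_per_gen = detected_once_fraction(matrix, annotation)
    return SuccessionSummary(
        total_is=total,
        is_per_tumor=per_tumor,
        is_per_patient=per_patient,
        generation_exclusive_fraction=generation_exclusive_fraction(matrix, annotation),
        detected_once_fraction=once_overall,
        detected_once_by_generation=once_per_gen,
        dominant_nonpersistent_fraction=dominant_nonpersistent_fraction(
            matrix, annotation, dominance=dominance
        ),
        prior_generation_fraction=prior_generation_fraction(matrix, annotation),
        pairwise_overlap=pairwise_overlap(
            matrix, annotation, denominator=overlap_denominator
        ),
    )
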