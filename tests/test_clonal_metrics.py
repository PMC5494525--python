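"""Succession statistics against set-algebra oracles and trivial layouts."""

import numpy as np
import pandas as pd
import pytest

from clonesucc.clonal_metrics import (
    GenerationAnnotation,
    detected_once_fraction,
    dominant_nonpersistent_fraction,
    generation_exclusive_fraction,
    is_counts,
    pairwise_overlap,
    prior_generation_fraction,
    summarize,
)
from clonesucc.is_processing import ContributionMatrix


def make_annotation(spec):
    """spec: {tumor_id: (patient, experiment, generation, parent)}"""
    table = pd.DataFrame.from_dict(
        spec, orient="index", columns=["patient", "experiment", "generation", "parent"]
    )
    table.index.name = "tumor_id"
    return GenerationAnnotation(table)


def make_matrix(detections, contributions=None):
    """detections: {tumor_id: set of IS labels}."""
    tumors = list(detections)
    is_ids = sorted({i for s in detections.values() for i in s})
    det = np.zeros((len(is_ids), len(tumors)), dtype=bool)
    for j, t in enumerate(tumors):
        for i, isid in enumerate(is_ids):
            det[i, j] = isid in detections[t]
    contrib = np.zeros_like(det, dtype=float)
    for j in range(len(tumors)):
        n = det[:, j].sum()
        if n:
            contrib[det[:, j], j] = 1.0 / n
    if contributions:
        for (isid, t), v in contributions.items():
            contrib[is_ids.index(isid), tumors.index(t)] = v
    return ContributionMatrix(
        is_ids=[(c, 1, "+") if isinstance(c, str) else c for c in is_ids],
        tumor_ids=tumors,
        contribution=contrib,
        detected=det,
    )


ANN3 = make_annotation(
    {
        "A1": ("P1", "E1", 1, None),
        "B1": ("P1", "E1", 2, "A1"),
        "B2": ("P1", "E1", 2, "A1"),
        "C1": ("P1", "E1", 3, "B1"),
    }
)


class TestIsCounts:
    def test_shared_is_counted_once(self):
        m = make_matrix({"A1": {"x"}, "B1": {"x"}, "B2": {"x"}, "C1": set()})
        total, per_tumor, per_patient = is_counts(m, ANN3)
        assert total == 1
        assert per_tumor == {"A1": 1, "B1": 1, "B2": 1, "C1": 0}
        assert per_patient == {"P1": 1}

    def test_matches_brute_force_on_synthetic(self, small_experiment, small_matrix):
        matrix, ann = small_matrix
        total, per_tumor, _ = is_counts(matrix, ann)
        # independent set counting over the detection frame
        det = matrix.detected_frame()
        assert total == int(det.any(axis=1).sum())
        for t in matrix.tumor_ids:
            assert per_tumor[t] == int(det[t].sum())


class TestGenerationExclusive:
    def test_disjoint_generations(self):
        m = make_matrix({"A1": {"a"}, "B1": {"b"}, "B2": {"c"}, "C1": {"d"}})
        assert generation_exclusive_fraction(m, ANN3) == 1.0

    def test_identical_generations(self):
        m = make_matrix({"A1": {"a"}, "B1": {"a"}, "B2": {"a"}, "C1": {"a"}})
        assert generation_exclusive_fraction(m, ANN3) == 0.0

    def test_reported_arithmetic(self):
        # 236 distinct IS of which 183 single-generation -> 78% rounded
        detections = {"A1": set(), "B1": set(), "B2": set(), "C1": set()}
        for i in range(183):
            detections["A1"].add(f"x{i}")
        for i in range(183, 236):
            detections["A1"].add(f"x{i}")
            detections["B1"].add(f"x{i}")
        m = make_matrix(detections)
        frac = generation_exclusive_fraction(m, ANN3)
        assert frac == pytest.approx(183 / 236)
        assert round(frac, 2) == 0.78


class TestDetectedOnce:
    def test_every_is_unique(self):
        m = make_matrix({"A1": {"a"}, "B1": {"b"}, "B2": {"c"}, "C1": {"d"}})
        overall, per_gen = detected_once_fraction(m, ANN3)
        assert overall == 1.0
        assert per_gen == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_shared_is_not_once(self):
        m = make_matrix({"A1": {"a"}, "B1": {"a"}, "B2": set(), "C1": set()})
        overall, per_gen = detected_once_fraction(m, ANN3)
        assert overall == 0.0
        assert per_gen[1] == 0.0 and per_gen[2] == 0.0

    def test_matches_brute_force_multiplicity(self, small_matrix):
        matrix, ann = small_matrix
        overall, _ = detected_once_fraction(matrix, ann)
        det = matrix.detected_frame().to_numpy()
        counts = det.sum(axis=1)
        assert overall == pytest.approx(
            (counts == 1).sum() / (counts > 0).sum()
        )

    def test_once_implies_generation_exclusive(self, small_matrix):
        matrix, ann = small_matrix
        det = matrix.detected_frame().to_numpy()
        gens = np.array([ann.generation(t) for t in matrix.tumor_ids])
        once = det.sum(axis=1) == 1
        exclusive = np.array(
            [len(set(gens[row])) == 1 if row.any() else False for row in det]
        )
        assert (exclusive[once]).all()


class TestDominantNonpersistent:
    def test_persistent_dominant(self):
        m = make_matrix(
            {"A1": {"a"}, "B1": {"a"}, "B2": {"a"}, "C1": {"a"}},
            contributions={(("a", 1, "+") if False else "a", "A1"): 1.0},
        )
        assert dominant_nonpersistent_fraction(m, ANN3) == 0.0

    def test_confined_dominant(self):
        m = make_matrix({"A1": {"a", "b"}, "B1": {"c"}, "B2": set(), "C1": set()},
                        contributions={("a", "A1"): 0.9, ("b", "A1"): 0.1})
        assert dominant_nonpersistent_fraction(m, ANN3) == 1.0

    def test_matches_exhaustive_scan(self, small_matrix):
        matrix, ann = small_matrix
        frac = dominant_nonpersistent_fraction(matrix, ann)
        det = matrix.detected_frame().to_numpy()
        gens = np.array([ann.generation(t) for t in matrix.tumor_ids])
        dominant_idx = np.where((matrix.contribution >= 0.5).any(axis=1))[0]
        expect = np.mean([len(set(gens[det[i]])) == 1 for i in dominant_idx])
        assert frac == pytest.approx(expect)


class TestPriorGeneration:
    def test_all_reused(self):
        m = make_matrix({"A1": {"a", "b"}, "B1": {"a"}, "B2": {"b"}, "C1": {"a"}})
        assert prior_generation_fraction(m, ANN3) == {"E1": 1.0}

    def test_all_new(self):
        m = make_matrix({"A1": {"a"}, "B1": {"b"}, "B2": {"c"}, "C1": {"d"}})
        assert prior_generation_fraction(m, ANN3) == {"E1": 0.0}

    def test_single_generation_experiment_is_missing(self):
        ann = make_annotation({"A1": ("P1", "E1", 1, None)})
        m = make_matrix({"A1": {"a"}})
        assert prior_generation_fraction(m, ann) == {"E1": None}


class TestPairwiseOverlap:
    def test_identical_and_disjoint(self):
        m = make_matrix({"A1": {"a"}, "B1": {"x", "y"}, "B2": {"x", "y"}, "C1": set()})
        ov = pairwise_overlap(m, ANN3)
        assert ov[("B1", "B2")] == 1.0
        m2 = make_matrix({"A1": {"a"}, "B1": {"x"}, "B2": {"y"}, "C1": set()})
        assert pairwise_overlap(m2, ANN3)[("B1", "B2")] == 0.0

    def test_smaller_denominator_flag(self):
        m = make_matrix({"A1": {"a"}, "B1": {"x", "y"}, "B2": {"x"}, "C1": set()})
        assert pairwise_overlap(m, ANN3)[("B1", "B2")] == pytest.approx(1 / 2)
        assert pairwise_overlap(m, ANN3, denominator="smaller")[("B1", "B2")] == 1.0

    def test_matches_set_oracle_on_synthetic(self, small_matrix):
        matrix, ann = small_matrix
        ov = pairwise_overlap(matrix, ann)
        det = matrix.detected_frame()
        for (a, b), val in ov.items():
            sa = set(det.index[det[a]])
            sb = set(det.index[det[b]])
            expect = len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
            assert val == pytest.approx(expect)


class TestSummaryInvariance:
    def test_permutation_invariance(self, small_matrix):
        matrix, ann = small_matrix
        perm = np.random.default_rng(0).permutation(len(matrix.is_ids))
        shuffled = ContributionMatrix(
            is_ids=[matrix.is_ids[i] for i in perm],
            tumor_ids=matrix.tumor_ids,
            contribution=matrix.contribution[perm],
            detected=matrix.detected[perm],
        )
        a = summarize(matrix, ann).to_dict()
        b = summarize(shuffled, ann).to_dict()
        assert a == b

    def test_annotation_validation(self):
        with pytest.raises(ValueError, match="generation"):
            make_annotation(
                {"A1": ("P1", "E1", 1, None), "B1": ("P1", "E1", 3, "A1")}
            )
        with pytest.raises(ValueError, match="parent"):
            make_annotation({"A1": ("P1", "E1", 2, None)})
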