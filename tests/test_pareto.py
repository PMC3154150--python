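"""Dominance, non-dominated filtering, front capping and representatives."""

import numpy as np
import pytest

from epiforge import ParetoFront, cap_front, dominates, pareto_front, representative
from epiforge.objectives import ObjectiveVector


def vec(values, ori=("min", "min", "max")):
    return ObjectiveVector(np.array(values, dtype=float), ori)


def brute_force_front(values, orientations):
    """O(n^2) oracle straight from the definition of dominance."""
    sign = np.array([1 if o == "min" else -1 for o in orientations])
    v = values * sign
    keep = []
    for j in range(len(v)):
        dominated = any(
            (v[i] <= v[j]).all() and (v[i] < v[j]).any()
            for i in range(len(v))
            if i != j
        )
        if not dominated:
            keep.append(j)
    return np.array(keep)


class TestDominates:
    def test_better_everywhere(self):
        assert dominates(vec([0.50, 0.51, 0.90]), vec([0.51, 0.52, 0.80]))

    def test_equal_vectors_do_not_dominate(self):
        a = vec([0.5, 0.5, 0.7])
        assert not dominates(a, a)

    def test_mutually_non_dominated(self):
        a = vec([0.50, 0.70], ("min", "max"))
        b = vec([0.51, 0.80], ("min", "max"))
        assert not dominates(a, b) and not dominates(b, a)

    def test_mismatched_orientations_rejected(self):
        with pytest.raises(ValueError):
            dominates(vec([0.5, 0.5], ("min", "min")), vec([0.5, 0.5], ("min", "max")))

    def test_strict_partial_order_on_random_triples(self, rng):
        ori = ("min", "max", "min")
        for _ in range(300):
            a, b, c = (
                ObjectiveVector(rng.integers(0, 4, 3).astype(float), ori)
                for _ in range(3)
            )
            assert not dominates(a, a)  # irreflexive
            if dominates(a, b):
                assert not dominates(b, a)  # antisymmetric
            if dominates(a, b) and dominates(b, c):
                assert dominates(a, c)  # transitive


class TestParetoFrontFilter:
    def test_single_vector_is_its_own_front(self):
        assert pareto_front([vec([0.5, 0.5, 0.7])]).tolist() == [0]

    def test_worked_two_objective_example(self):
        pts = np.array([[0.51, 0.80], [0.50, 0.70], [0.52, 0.90], [0.51, 0.60]])
        idx = pareto_front(pts, ("min", "max"))
        assert sorted(pts[i].tolist() for i in idx) == [
            [0.50, 0.70],
            [0.51, 0.80],
            [0.52, 0.90],
        ]

    def test_duplicates_all_retained(self):
        pts = np.array([[0.5, 0.8], [0.5, 0.8], [0.6, 0.7]])
        idx = pareto_front(pts, ("min", "max"))
        assert idx.tolist() == [0, 1]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            d = int(rng.integers(3, 6))
            m = int(rng.integers(1, 30))
            ori = tuple(rng.choice(["min", "max"], d))
            values = rng.integers(0, 5, size=(m, d)).astype(float)
            got = pareto_front(values, ori)
            np.testing.assert_array_equal(np.sort(got), brute_force_front(values, ori))

    def test_idempotent(self, rng):
        values = rng.integers(0, 5, size=(40, 3)).astype(float)
        ori = ("min", "min", "max")
        first = pareto_front(values, ori)
        again = pareto_front(values[first], ori)
        assert len(again) == len(first)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])


class TestCapFront:
    def test_small_front_unchanged(self):
        values = np.array([[0.5, 0.8], [0.6, 0.9]])
        front = ParetoFront(values, ("min", "max"))
        assert cap_front(front, 100) is front

    def test_elbow_beats_extremes(self):
        # both objectives minimized; normalized distances 1, 1, ~0.566
        front = ParetoFront(
            np.array([[0.0, 1.0], [1.0, 0.0], [0.4, 0.4]]), ("min", "min")
        )
        capped = cap_front(front, 1)
        np.testing.assert_allclose(capped.values, [[0.4, 0.4]])

    def test_output_size_and_subset(self, rng):
        values = rng.random((50, 2))
        idx = pareto_front(values, ("min", "max"))
        front = ParetoFront(values[idx], ("min", "max"))
        for cap in (1, 3, len(front), len(front) + 5):
            capped = cap_front(front, cap)
            assert len(capped) == min(len(front), cap)
            # subset of the input front, still mutually non-dominated
            for row in capped.values:
                assert (row == front.values).all(axis=1).any()
            assert len(pareto_front(capped.values, ("min", "max"))) == len(capped)

    def test_crowding_method_also_caps(self, rng):
        values = np.array([[0.0, 1.0], [0.5, 0.5], [0.6, 0.4], [1.0, 0.0]])
        front = ParetoFront(values, ("min", "min"))
        capped = cap_front(front, 2, method="crowding")
        assert len(capped) == 2

    def test_invalid_cap_rejected(self):
        front = ParetoFront(np.array([[0.5, 0.8]]), ("min", "max"))
        with pytest.raises(ValueError):
            cap_front(front, 0)


class TestRepresentative:
    def test_singleton_front(self):
        front = ParetoFront(np.array([[0.5, 0.9]]), ("min", "max"))
        assert representative(front) == 0

    def test_hand_computed_distances(self):
        # ideal = (0.50, 0.90); distances ~0.300, 0.020, 0.100
        front = ParetoFront(
            np.array([[0.50, 0.60], [0.52, 0.90], [0.51, 0.80]]), ("min", "max")
        )
        assert representative(front) == 1

    def test_never_dominated(self, rng):
        values = rng.random((40, 3))
        ori = ("min", "min", "max")
        idx = pareto_front(values, ori)
        front = ParetoFront(values[idx], ori)
        rep = front.member_vector(representative(front))
        assert not any(
            dominates(front.member_vector(i), rep) for i in range(len(front))
        )

    def test_normalization_guards_unbounded_objective(self):
        # raw distance would let the chi-square swamp the accuracies
        front = ParetoFront(
            np.array([[0.50, 0.86, 40.0], [0.55, 0.60, 0.5]]),
            ("min", "max", "min"),
        )
        assert representative(front, normalize=True) != representative(
            front, normalize=False
        )


def test_front_validation_rejects_dominated_members():
    with pytest.raises(ValueError, match="non-dominated"):
        ParetoFront(np.array([[0.5, 0.9], [0.6, 0.8]]), ("min", "max"))
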