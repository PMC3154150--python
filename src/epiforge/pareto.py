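"""Pareto dominance, non-dominated filtering, front capping and the
representative-dataset choice.

Selection in the evolution strategy is purely rank-1 Pareto: all
non-dominated datasets survive.  When the front outgrows the configured cap
(needed once a fourth or fifth objective inflates the front), the "elbow"
members are kept: those closest, after per-objective min-max normalization,
to the ideal point formed by the per-objective optima — datasets good in
several dimensions at once rather than extreme in a single one.  The same
ideal-point distance, on raw accuracy scales when all objectives are
accuracies, picks the single representative dataset that summarizes a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ContingencyTable
from .objectives import MAX, MIN, ObjectiveVector

__all__ = ["ParetoFront", "dominates", "pareto_front", "cap_front",
           "representative"]


def _as_matrix(
    vectors, orientations: Sequence[str] | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(vectors, np.ndarray):
        if orientations is None:
            raise ValueError("orientations are required with a plain array")
        return np.asarray(vectors, dtype=float), tuple(orientations)
    vecs = list(vectors)
    if not vecs:
        raise ValueError("at least one objective vector is required")
    ori = vecs[0].orientations
    if any(v.orientations != ori for v in vecs):
        raise ValueError("all vectors must share one set of orientations")
    return np.array([v.values for v in vecs], dtype=float), ori


def _minimized(values: np.ndarray, orientations: Sequence[str]) -> np.ndarray:
    """Flip maximized columns so that smaller is better everywhere."""
    sign = np.array([1.0 if o == MIN else -1.0 for o in orientations])
    return values * sign


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` is at least as good as ``b`` in every objective and
    strictly better in at least one (a strict partial order)."""
    if a.orientations != b.orientations:
        raise ValueError("vectors must share orientations to be compared")
    av = _minimized(a.values, a.orientations)
    bv = _minimized(b.values, b.orientations)
    return bool((av <= bv).all() and (av < bv).any())


def _nondominated_mask(mini: np.ndarray, block: int = 128) -> np.ndarray:
    """Boolean mask of non-dominated rows of an all-minimized matrix.

    Deduplicates rows, then sweeps the unique rows in increasing order of
    coordinate sum in blocks.  A dominator has a strictly smaller sum than
    anything it dominates (rows being distinct), so each block need only be
    screened against the running non-dominated archive — transitivity
    guarantees checking dominated points is unnecessary — plus a small
    pairwise check within the block.
    """
    uniq, inverse = np.unique(mini, axis=0, return_inverse=True)
    u = len(uniq)
    order = np.argsort(uniq.sum(axis=1), kind="stable")
    nd_u = np.zeros(u, dtype=bool)
    archive = np.empty((0, mini.shape[1]))
    for lo in range(0, u, block):
        idx = order[lo : lo + block]
        rows = uniq[idx]
        if len(archive):
            dom = (archive[:, None, :] <= rows[None, :, :]).all(axis=-1)
            alive = ~dom.any(axis=0)
            idx, rows = idx[alive], rows[alive]
            if len(rows) == 0:
                continue
        # within-block: uniq[i] <= uniq[j] everywhere with i != j implies
        # strict dominance (rows are distinct)
        le_all = (rows[:, None, :] <= rows[None, :, :]).all(axis=-1)
        keep = le_all.sum(axis=0) == 1
        nd_u[idx[keep]] = True
        archive = np.concatenate([archive, rows[keep]])
    return nd_u[inverse]


def pareto_front(
    vectors, orientations: Sequence[str] | None = None
) -> np.ndarray:
    """Indices of the non-dominated members, in stable input order.

    Accepts a list of :class:`ObjectiveVector` or a (m, d) array plus
    orientations.  Members with identical vectors are all retained: they
    are distinct datasets with equal scores, and equal vectors never
    dominate each other.
    """
    values, ori = _as_matrix(vectors, orientations)
    if values.ndim != 2 or len(values) == 0:
        raise ValueError("pareto_front requires a non-empty list of vectors")
    return np.flatnonzero(_nondominated_mask(_minimized(values, ori)))


@dataclass(frozen=True)
class ParetoFront:
    """A set of mutually non-dominated datasets with their objective values.

    ``values`` is (m, d); ``counts`` optionally carries the member datasets
    in count form, (m, 2, 3^k).
    """

    values: np.ndarray
    orientations: tuple[str, ...]
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.orientations):
            raise ValueError("values must be (members, objectives)")
        if len(values) == 0:
            raise ValueError("a Pareto front is never empty")
        mini = _minimized(values, self.orientations)
        if not _nondominated_mask(mini).all():
            raise ValueError("front members must be mutually non-dominated")
        if self.counts is not None and len(self.counts) != len(values):
            raise ValueError("counts must pair one dataset per member")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "orientations", tuple(self.orientations))

    def __len__(self) -> int:
        return len(self.values)

    def member_vector(self, i: int) -> ObjectiveVector:
        return ObjectiveVector(self.values[i], self.orientations)

    def member_table(self, i: int) -> ContingencyTable:
        if self.counts is None:
            raise ValueError("this front does not carry member datasets")
        return ContingencyTable(self.counts[i, 0], self.counts[i, 1])

    def subset(self, indices: np.ndarray) -> "ParetoFront":
        counts = None if self.counts is None else self.counts[indices]
        return ParetoFront(self.values[indices], self.orientations, counts)


def _normalized_ideal_distance(mini: np.ndarray) -> np.ndarray:
    """Distance to the ideal point after per-objective min-max scaling.

    Each objective is mapped to [0, 1] with 0 at the front's best value; a
    constant objective contributes nothing.  The ideal point is the origin.
    """
    lo = mini.min(axis=0)
    span = mini.max(axis=0) - lo
    span[span == 0] = 1.0
    scaled = (mini - lo) / span
    return np.sqrt((scaled**2).sum(axis=1))


def _crowding_distance(mini: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance (larger = less crowded / more extreme)."""
    m, d = mini.shape
    crowd = np.zeros(m)
    for j in range(d):
        order = np.argsort(mini[:, j], kind="stable")
        col = mini[order, j]
        span = col[-1] - col[0]
        crowd[order[0]] = crowd[order[-1]] = np.inf
        if span > 0 and m > 2:
            crowd[order[1:-1]] += (col[2:] - col[:-2]) / span
    return crowd


def _cap_indices(mini: np.ndarray, cap: int, method: str) -> np.ndarray:
    """Sorted indices of the ``cap`` members kept by the elbow criterion."""
    if method == "ideal_distance":
        score = _normalized_ideal_distance(mini)
    elif method == "crowding":
        score = _crowding_distance(mini)
    else:
        raise ValueError("method must be 'ideal_distance' or 'crowding'")
    return np.sort(np.argsort(score, kind="stable")[:cap])


def cap_front(front: ParetoFront, cap: int, method: str = "ideal_distance") -> ParetoFront:
    """Limit a front to its ``cap`` most central ("elbow") members.

    Unchanged when the front already fits.  With ``method="ideal_distance"``
    (default) the members closest to the normalized ideal point are kept,
    which favours datasets good in more than one objective over
    single-objective extremes.  ``method="crowding"`` keeps the members with
    the *smallest* NSGA-II crowding distance instead (extremes have infinite
    crowding distance, so they are culled first).  Ties break by stable
    input order; the output preserves input order.
    """
    if cap < 1:
        raise ValueError("cap must be at least 1")
    if len(front) <= cap:
        return front
    mini = _minimized(front.values, front.orientations)
    keep = _cap_indices(mini, cap, method)
    return front.subset(keep)


def representative(front: ParetoFront, normalize: bool | None = None) -> int:
    """Index of the front member closest to the per-objective optima.

    The ideal vector collects the best value any front member attains on
    each objective; the representative minimizes Euclidean distance to it.
    When all objectives are MDR accuracies they share the [0.5, 1] scale and
    raw distances are used; if an unbounded objective (the HWE chi-square)
    is present, all objectives are min-max normalized over the front first
    so it cannot swamp the distance.  ``normalize`` overrides the automatic
    choice.  Ties break by stable order.
    """
    mini = _minimized(front.values, front.orientations)
    if normalize is None:
        # accuracies live in [0.5, 1]; anything outside betrays an
        # incommensurate objective such as the chi-square
        raw = np.abs(mini)
        normalize = bool((raw < 0.5 - 1e-12).any() or (raw > 1 + 1e-12).any())
    if normalize:
        dist = _normalized_ideal_distance(mini)
    else:
        ideal = mini.min(axis=0)
        dist = np.sqrt(((mini - ideal) ** 2).sum(axis=1))
    return int(np.argmin(dist))
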