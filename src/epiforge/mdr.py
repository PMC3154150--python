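"""Multifactor Dimensionality Reduction (MDR) accuracies on contingency tables.

MDR partitions subjects by their multi-locus genotype, labels each genotype
cell high-risk when it holds more cases than controls, and scores the
partition by the fraction of subjects the high/low-risk labeling classifies
correctly.  For a balanced design the accuracy is

    acc = sum_cells max(cases_c, controls_c) / n

which ranges from 0.5 (every cell balanced) to 1.0 (every cell pure).  Tied
and empty cells may be labeled either way without changing the value; we
label them low-risk by convention.

The batch path used by the evolution loop exploits the identity
``max(a, b) = (a + b + |a - b|) / 2``: accuracy is ``0.5 + sum|case - ctrl|
/ (2n)`` over the marginalized cells, so only a single case-minus-control
differential table needs to be marginalized per SNP subset.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .data_model import ContingencyTable

__all__ = [
    "all_subsets",
    "marginalize",
    "mdr_accuracy",
    "max_order_accuracy",
    "classify_cells",
]


def _validate_subset(subset: Sequence[int], n_snps: int) -> tuple[int, ...]:
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("SNP subset must be non-empty")
    if any(i < 0 or i >= n_snps for i in subset):
        raise ValueError(f"SNP indices must lie in [0, {n_snps}), got {subset}")
    if any(b <= a for a, b in zip(subset, subset[1:])):
        raise ValueError(f"SNP subset must be strictly increasing, got {subset}")
    return subset


def all_subsets(n_snps: int, order: int) -> Iterable[tuple[int, ...]]:
    """All C(k, order) strictly increasing SNP index tuples of the given order."""
    return combinations(range(n_snps), order)


def marginalize(counts: np.ndarray, n_snps: int, subset: Sequence[int]) -> np.ndarray:
    """Collapse a 3^k cell-count vector onto the 3^m cells of a SNP subset.

    Works on any array whose last axis has length 3^k (leading axes are
    batch dimensions).  Marginalization is associative: collapsing to a
    superset and then to the subset equals collapsing directly.
    """
    subset = _validate_subset(subset, n_snps)
    counts = np.asarray(counts)
    lead = counts.shape[:-1]
    nd = counts.reshape(lead + (3,) * n_snps)
    drop = tuple(
        ax + len(lead) for ax in range(n_snps) if ax not in subset
    )
    marg = nd.sum(axis=drop) if drop else nd
    return marg.reshape(lead + (3 ** len(subset),))


def classify_cells(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """High-risk (True) / low-risk (False) label per genotype cell.

    A cell is high-risk when it holds strictly more cases than controls;
    ties and empty cells are low-risk.  The convention is display-only: the
    accuracy value is unchanged whichever way tied cells are labeled.
    """
    return np.asarray(case) > np.asarray(control)


def mdr_accuracy(table: ContingencyTable, subset: Sequence[int]) -> float:
    """MDR accuracy of one SNP subset on a balanced table.

    Marginalizes onto the subset's 3^|subset| cells and scores the
    majority-class labeling.  Only defined for balanced tables: with
    unequal class totals the 0.5 floor and the model-agnostic symmetry of
    the accuracy both break down.
    """
    if not table.is_balanced:
        raise ValueError(
            "MDR accuracy requires an equal number of cases and controls "
            f"(got {table.n_cases} cases of {table.n_subjects} subjects)"
        )
    subset = _validate_subset(subset, table.n_snps)
    case = marginalize(table.case_counts, table.n_snps, subset)
    ctrl = marginalize(table.control_counts, table.n_snps, subset)
    return float(np.maximum(case, ctrl).sum() / table.n_subjects)


def max_order_accuracy(table: ContingencyTable, order: int) -> float:
    """Largest MDR accuracy over all SNP subsets of the given order.

    This is the per-order *attribute* of a dataset: the strongest
    ``order``-way marker-disease association it contains.  For
    ``order == k`` there is a single subset (all SNPs) and the value is the
    full-order accuracy.  Subsets are enumerated exhaustively (k <= 5 in
    practice, so at most 31 subsets).
    """
    if not 1 <= order <= table.n_snps:
        raise ValueError(
            f"order must lie in [1, {table.n_snps}], got {order}"
        )
    return max(
        mdr_accuracy(table, subset) for subset in all_subsets(table.n_snps, order)
    )


def max_abs_diff_by_order(
    diff: np.ndarray, n_snps: int, orders: Sequence[int]
) -> dict[int, np.ndarray]:
    """Batch kernel: max over subsets of sum|marginalized case-ctrl diff|.

    ``diff`` has shape (B, 3^k).  Returns, per requested order, a (B,)
    integer array ``s`` such that the order's attribute accuracy is
    ``0.5 + s / (2n)``.
    """
    out: dict[int, np.ndarray] = {}
    for order in orders:
        best = None
        for subset in all_subsets(n_snps, order):
            s = np.abs(marginalize(diff, n_snps, subset)).sum(axis=-1)
            best = s if best is None else np.maximum(best, s)
        out[order] = best
    return out
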