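"""Objective vectors: per-order MDR attributes and the HWE chi-square.

Each dataset is scored on a small vector of *attributes* that drive Pareto
selection: for every interaction order being suppressed, the largest MDR
accuracy over all SNP subsets of that order (minimized); the full-order
accuracy over all k SNPs (maximized); and optionally a Hardy-Weinberg
disequilibrium statistic (minimized) so that evolved SNPs would survive
standard genotyping quality-control filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import ContingencyTable
from .mdr import marginalize, max_abs_diff_by_order, max_order_accuracy

__all__ = ["ObjectiveSpec", "ObjectiveVector", "hwe_chi_square", "evaluate",
           "evaluate_counts"]

MIN, MAX = "min", "max"


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which attributes a run optimizes, and in which direction.

    Parameters
    ----------
    n_snps:
        Number of SNPs k; the maximized attribute is always the full
        k-way MDR accuracy.
    minimized_orders:
        Interaction orders (all < k) whose maximum MDR accuracy is driven
        toward 0.5, e.g. ``(1, 2)`` for "no marginal or pairwise effects".
    hwe:
        Include the Hardy-Weinberg chi-square as an additional minimized
        objective.
    hwe_aggregate:
        How per-SNP chi-squares combine into one attribute: ``"max"``
        (default; guards the worst SNP, which is what QC filters act on)
        or ``"sum"``.
    hwe_pooled:
        Compute HWE on pooled cases + controls (default) or on controls
        only.
    """

    n_snps: int
    minimized_orders: tuple[int, ...] = (1, 2)
    hwe: bool = False
    hwe_aggregate: str = "max"
    hwe_pooled: bool = True

    def __post_init__(self) -> None:
        orders = tuple(sorted(int(o) for o in self.minimized_orders))
        if len(set(orders)) != len(orders):
            raise ValueError("minimized_orders must be distinct")
        if any(o < 1 or o >= self.n_snps for o in orders):
            raise ValueError(
                f"minimized orders must lie strictly below n_snps={self.n_snps}"
            )
        if self.hwe_aggregate not in ("max", "sum"):
            raise ValueError("hwe_aggregate must be 'max' or 'sum'")
        object.__setattr__(self, "minimized_orders", orders)

    @property
    def maximized_order(self) -> int:
        return self.n_snps

    @property
    def n_objectives(self) -> int:
        return len(self.minimized_orders) + 1 + int(self.hwe)

    @property
    def orientations(self) -> tuple[str, ...]:
        ori = [MIN] * len(self.minimized_orders) + [MAX]
        if self.hwe:
            ori.append(MIN)
        return tuple(ori)

    @property
    def labels(self) -> tuple[str, ...]:
        lab = [f"acc_{o}way" for o in self.minimized_orders]
        lab.append(f"acc_{self.n_snps}way")
        if self.hwe:
            lab.append("hwe_chi2")
        return tuple(lab)


@dataclass(frozen=True)
class ObjectiveVector:
    """A dataset's attribute values paired with optimization directions."""

    values: np.ndarray
    orientations: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.orientations),):
            raise ValueError("one orientation is required per objective value")
        if any(o not in (MIN, MAX) for o in self.orientations):
            raise ValueError(f"orientations must be '{MIN}' or '{MAX}'")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.orientations)


def _chi_square_from_genotype_counts(counts: np.ndarray) -> np.ndarray:
    """HWE chi-square per SNP from genotype counts (..., 3) = (n0, n1, n2)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1, keepdims=True)
    p = (2 * counts[..., 0] + counts[..., 1]) / (2 * n[..., 0])
    q = 1.0 - p
    expected = np.stack([p**2, 2 * p * q, q**2], axis=-1) * n
    # Monomorphic SNPs (p in {0,1}) put zero expectation in some cells while
    # the observed count there is also zero: no measurable HWE deviation.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    terms = np.where(expected > 0, terms, 0.0)
    return terms.sum(axis=-1)


def hwe_chi_square(
    table: ContingencyTable, snp_index: int, pooled: bool = True
) -> float:
    """Chi-square deviation from Hardy-Weinberg proportions for one SNP.

    From the genotype counts (n0, n1, n2) the allele frequency is
    p = (2 n0 + n1) / 2n; expected counts are (n p^2, 2 n p (1-p),
    n (1-p)^2) and the statistic is the usual sum of squared Pearson
    residuals.  Zero means observed counts match HWE exactly.  A
    monomorphic SNP yields 0 (no deviation is measurable).
    """
    if not 0 <= snp_index < table.n_snps:
        raise ValueError(f"snp_index must lie in [0, {table.n_snps})")
    cells = table.pooled() if pooled else table.control_counts
    geno = marginalize(cells, table.n_snps, (snp_index,))
    return float(_chi_square_from_genotype_counts(geno))


def evaluate(table: ContingencyTable, spec: ObjectiveSpec) -> ObjectiveVector:
    """Score one dataset: per-order attributes plus optional HWE statistic."""
    if table.n_snps != spec.n_snps:
        raise ValueError(
            f"table has {table.n_snps} SNPs but spec expects {spec.n_snps}"
        )
    if not table.is_balanced:
        raise ValueError("objective evaluation requires a balanced table")
    values = [
        max_order_accuracy(table, o) for o in spec.minimized_orders
    ]
    values.append(max_order_accuracy(table, spec.n_snps))
    if spec.hwe:
        chis = [
            hwe_chi_square(table, j, pooled=spec.hwe_pooled)
            for j in range(spec.n_snps)
        ]
        values.append(max(chis) if spec.hwe_aggregate == "max" else sum(chis))
    return ObjectiveVector(np.array(values), spec.orientations)


def evaluate_counts(counts: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Vectorized evaluation of a batch of count-form datasets.

    ``counts`` has shape (B, 2, 3^k) (case counts first).  Returns a
    (B, n_objectives) float array in the spec's objective order.  Equals
    per-table :func:`evaluate` on every row.
    """
    counts = np.asarray(counts)
    B = counts.shape[0]
    k = spec.n_snps
    n = int(counts[0].sum()) if B else 0
    diff = (counts[:, 0, :] - counts[:, 1, :]).astype(np.int64)
    orders = list(spec.minimized_orders) + [k]
    smax = max_abs_diff_by_order(diff, k, orders)
    # (n + s) / 2 is the integer count of correctly classified subjects, so
    # this division yields bit-identical floats to the per-table path
    cols = [(n + smax[o]) / (2.0 * n) for o in orders]
    out = np.column_stack(cols)
    if spec.hwe:
        cells = counts.sum(axis=1) if spec.hwe_pooled else counts[:, 1, :]
        geno = np.stack(
            [marginalize(cells, k, (j,)) for j in range(k)], axis=1
        )  # (B, k, 3)
        chi = _chi_square_from_genotype_counts(geno)
        agg = chi.max(axis=1) if spec.hwe_aggregate == "max" else chi.sum(axis=1)
        out = np.column_stack([out, agg])
    return out
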