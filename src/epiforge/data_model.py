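"""Balanced case-control genotype datasets and their contingency-table form.

A dataset is the *individual* of the evolution strategy: ``n`` subjects
(half cases, half controls) typed at ``k`` bi-allelic SNPs, each genotype
coded 0 (homozygous), 1 (heterozygous) or 2 (homozygous).  Because every
score used downstream (MDR accuracies, Hardy-Weinberg chi-square) depends
only on how many subjects of each class fall in each of the 3^k genotype
cells, subjects are exchangeable within a cell and the per-class cell-count
table is a lossless sufficient statistic.  All heavy computation therefore
operates on :class:`ContingencyTable` (or raw count arrays); genotype
matrices are materialized only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GENOTYPE_PROBS",
    "GenotypeDataset",
    "ContingencyTable",
    "cell_probabilities",
    "init_dataset",
    "init_counts",
    "to_contingency",
    "mutate",
    "mutate_counts",
]

#: Genotype frequencies at initialization: Hardy-Weinberg proportions for a
#: minor/major allele frequency of 0.5.
GENOTYPE_PROBS = (0.25, 0.5, 0.25)


def _powers(n_snps: int) -> np.ndarray:
    """Place values of each SNP in the big-endian cell index."""
    return 3 ** np.arange(n_snps - 1, -1, -1)


def cell_index(genotypes: np.ndarray) -> np.ndarray:
    """Map genotype rows (n, k) to cell indices in [0, 3^k)."""
    genotypes = np.asarray(genotypes)
    return genotypes @ _powers(genotypes.shape[-1])


def cell_probabilities(n_snps: int) -> np.ndarray:
    """Probability of each of the 3^k genotype cells under independent SNPs
    at Hardy-Weinberg proportions with MAF 0.5."""
    p = np.array(GENOTYPE_PROBS)
    out = p
    for _ in range(n_snps - 1):
        out = np.outer(out, p).ravel()
    return out


@dataclass(frozen=True)
class GenotypeDataset:
    """A balanced case-control cohort: genotype matrix plus status vector."""

    genotypes: np.ndarray  #: (n, k) array with entries in {0, 1, 2}
    status: np.ndarray  #: (n,) array with entries in {0, 1}; 1 = case

    def __post_init__(self) -> None:
        genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        status = np.ascontiguousarray(self.status, dtype=np.int8)
        if genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d (subjects x SNPs) array")
        if status.shape != (genotypes.shape[0],):
            raise ValueError("status length must equal the number of subjects")
        n = genotypes.shape[0]
        if n == 0 or n % 2:
            raise ValueError(
                f"n_subjects must be even and positive (got {n}): the design "
                "is a balanced case-control study"
            )
        if not np.isin(genotypes, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        if int(status.sum()) != n // 2:
            raise ValueError(
                f"dataset must hold exactly {n // 2} cases and {n // 2} "
                f"controls (got {int(status.sum())} cases)"
            )
        object.__setattr__(self, "genotypes", genotypes)
        object.__setattr__(self, "status", status)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class ContingencyTable:
    """Per-class subject counts over the 3^k genotype cells.

    Cell indexing is big-endian in the SNPs: a genotype vector
    (g_1, ..., g_k) maps to ``sum_j g_j * 3^(k-1-j)``.
    """

    case_counts: np.ndarray
    control_counts: np.ndarray
    n_snps: int = field(default=0)

    def __post_init__(self) -> None:
        case = np.ascontiguousarray(self.case_counts, dtype=np.int64)
        ctrl = np.ascontiguousarray(self.control_counts, dtype=np.int64)
        k = self.n_snps or int(round(np.log(case.size) / np.log(3)))
        if case.shape != (3**k,) or ctrl.shape != (3**k,):
            raise ValueError(
                f"count vectors must have length 3^{k} = {3**k}, "
                f"got {case.shape} and {ctrl.shape}"
            )
        if (case < 0).any() or (ctrl < 0).any():
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "case_counts", case)
        object.__setattr__(self, "control_counts", ctrl)
        object.__setattr__(self, "n_snps", k)

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset) -> "ContingencyTable":
        k = dataset.n_snps
        cells = cell_index(dataset.genotypes)
        case = np.bincount(cells[dataset.status == 1], minlength=3**k)
        ctrl = np.bincount(cells[dataset.status == 0], minlength=3**k)
        return cls(case, ctrl, k)

    @property
    def n_subjects(self) -> int:
        return int(self.case_counts.sum() + self.control_counts.sum())

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def is_balanced(self) -> bool:
        return self.case_counts.sum() == self.control_counts.sum()

    def pooled(self) -> np.ndarray:
        """Case + control counts per cell."""
        return self.case_counts + self.control_counts

    def to_dataset(self) -> GenotypeDataset:
        """Materialize a genotype matrix in canonical subject order.

        Subjects carry no identity in the count representation, so the
        export order is a convention: cases first, then controls, each
        class sorted by cell index.
        """
        k = self.n_snps
        cells = np.arange(3**k)
        digits = (cells[:, None] // _powers(k)) % 3
        case_rows = np.repeat(digits, self.case_counts, axis=0)
        ctrl_rows = np.repeat(digits, self.control_counts, axis=0)
        genotypes = np.vstack([case_rows, ctrl_rows])
        status = np.concatenate(
            [np.ones(len(case_rows), dtype=np.int8), np.zeros(len(ctrl_rows), dtype=np.int8)]
        )
        return GenotypeDataset(genotypes, status)


def to_contingency(dataset: GenotypeDataset) -> ContingencyTable:
    """Collapse a genotype matrix to its per-class cell-count table.

    Lossless for every downstream score (MDR accuracy, HWE chi-square),
    though subject identity and row order are discarded.
    """
    return ContingencyTable.from_dataset(dataset)


def init_dataset(
    n_subjects: int, n_snps: int, rng: np.random.Generator
) -> GenotypeDataset:
    """Random balanced dataset: half cases, genotypes i.i.d. at Hardy-Weinberg
    proportions for allele frequency 0.5, i.e. P(0, 1, 2) = (0.25, 0.5, 0.25).
    """
    if n_subjects <= 0 or n_subjects % 2:
        raise ValueError(
            f"n_subjects must be even and positive (got {n_subjects}): a "
            "balanced study assigns equal numbers of cases and controls"
        )
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    genotypes = rng.choice(3, size=(n_subjects, n_snps), p=GENOTYPE_PROBS)
    half = n_subjects // 2
    status = np.concatenate(
        [np.ones(half, dtype=np.int8), np.zeros(half, dtype=np.int8)]
    )
    return GenotypeDataset(genotypes.astype(np.int8), status)


def init_counts(
    n_datasets: int, n_subjects: int, n_snps: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_datasets`` random datasets directly at the count level.

    Returns an int64 array of shape (n_datasets, 2, 3^k); slice [:, 0] is
    case counts and [:, 1] control counts.  Drawing each class's cell counts
    from a Multinomial(n/2, HWE cell probabilities) is exactly the
    distribution obtained by tabulating an i.i.d. genotype matrix.
    """
    if n_subjects <= 0 or n_subjects % 2:
        raise ValueError(f"n_subjects must be even and positive (got {n_subjects})")
    half = n_subjects // 2
    probs = cell_probabilities(n_snps)
    counts = rng.multinomial(half, probs, size=(n_datasets, 2))
    return counts.astype(np.int64)


def _mutate_matrix(
    parent: GenotypeDataset,
    rate: float,
    rng: np.random.Generator,
    resample_same: bool,
) -> GenotypeDataset:
    genotypes = parent.genotypes.copy()
    hit = rng.random(genotypes.shape) < rate
    n_hit = int(hit.sum())
    if n_hit:
        old = genotypes[hit].astype(np.int64)
        if resample_same:
            new = rng.integers(0, 3, size=n_hit)
        else:
            new = (old + 1 + rng.integers(0, 2, size=n_hit)) % 3
        genotypes[hit] = new.astype(np.int8)
    return GenotypeDataset(genotypes, parent.status)


def mutate_counts(
    counts: np.ndarray,
    n_subjects: int,
    rate: float,
    rng: np.random.Generator,
    resample_same: bool = False,
) -> np.ndarray:
    """Mutate a batch of count-form datasets in place; returns ``counts``.

    ``counts`` has shape (B, 2, 3^k).  For each dataset the number of
    mutation events is Binomial(n*k, rate) — the count of hit entries in an
    equivalent genotype matrix.  Events are applied sequentially: each picks
    a class (uniform, classes being equal-sized), a cell with probability
    proportional to that class's current counts (subjects in a cell are
    exchangeable), a SNP uniformly, and moves one subject to the cell given
    by the re-drawn genotype at that SNP.  Batched over datasets in rounds,
    one event per dataset per round, which preserves the sequential
    within-dataset semantics.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must lie in [0, 1], got {rate}")
    B, _, C = counts.shape
    k = int(round(np.log(C) / np.log(3)))
    half = n_subjects // 2
    powers = _powers(k)
    n_events = rng.binomial(n_subjects * k, rate, size=B)
    for r in range(int(n_events.max()) if B else 0):
        idx = np.flatnonzero(n_events > r)
        a = idx.size
        cls = rng.integers(0, 2, size=a)
        sel = counts[idx, cls, :]
        cdf = np.cumsum(sel, axis=1)
        u = rng.random(a) * half
        cell = np.minimum((cdf <= u[:, None]).sum(axis=1), C - 1)
        snp = rng.integers(0, k, size=a)
        place = powers[snp]
        g = (cell // place) % 3
        if resample_same:
            g_new = rng.integers(0, 3, size=a)
        else:
            g_new = (g + 1 + rng.integers(0, 2, size=a)) % 3
        new_cell = cell + (g_new - g) * place
        counts[idx, cls, cell] -= 1
        counts[idx, cls, new_cell] += 1
    return counts


def _mutate_table(
    parent: ContingencyTable,
    rate: float,
    rng: np.random.Generator,
    resample_same: bool,
) -> ContingencyTable:
    counts = np.stack([parent.case_counts, parent.control_counts])[None, ...].copy()
    mutate_counts(counts, parent.n_subjects, rate, rng, resample_same)
    return ContingencyTable(counts[0, 0], counts[0, 1], parent.n_snps)


def mutate(
    parent: GenotypeDataset | ContingencyTable,
    rate: float,
    rng: np.random.Generator,
    resample_same: bool = False,
):
    """Mutate each genotype entry independently with probability ``rate``.

    A mutated entry is replaced by one of the two *other* genotype states,
    chosen uniformly, so the nominal rate is the realized change rate.  With
    ``resample_same=True`` the new state is drawn uniformly from all three,
    which silently lowers the effective change rate to 2/3 of nominal; the
    option exists for sensitivity checks.  Case/control status is never
    touched.  Accepts either representation and returns the same type;
    the two paths are distributionally identical because subjects within a
    genotype cell are exchangeable.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must lie in [0, 1], got {rate}")
    if isinstance(parent, GenotypeDataset):
        return _mutate_matrix(parent, rate, rng, resample_same)
    if isinstance(parent, ContingencyTable):
        return _mutate_table(parent, rate, rng, resample_same)
    raise TypeError(f"cannot mutate object of type {type(parent).__name__}")
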