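"""Random-search control: the Pareto front of a large sample of random
datasets, maintained in a streaming fashion.

This is the null the evolution strategy is compared against: how strong a
k-way interaction (and how weak the lower orders) can be found by sheer
sampling variation among millions of balanced random datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import init_counts
from .objectives import ObjectiveSpec, ObjectiveVector, evaluate_counts
from .pareto import ParetoFront, _minimized, _nondominated_mask, representative

__all__ = ["RandomSearchResult", "random_search"]


@dataclass(frozen=True)
class RandomSearchResult:
    """Final non-dominated set of the random sample and its representative."""

    front: ParetoFront
    representative_index: int
    n_datasets: int
    seed: int
    spec: ObjectiveSpec | None = None

    @property
    def representative_vector(self) -> ObjectiveVector:
        return self.front.member_vector(self.representative_index)

    @property
    def representative_table(self):
        return self.front.member_table(self.representative_index)


def random_search(
    n_datasets: int,
    n_subjects: int,
    spec: ObjectiveSpec,
    seed: int = 0,
    batch_size: int = 50_000,
    merge_chunk: int = 4_000,
) -> RandomSearchResult:
    """Draw ``n_datasets`` random balanced datasets and keep their Pareto front.

    Datasets are drawn at the count level: each class's cell counts come
    from a Multinomial(n/2, HWE cell probabilities), exactly the
    distribution obtained by tabulating an i.i.d. genotype matrix at MAF
    0.5.  The non-dominated set is maintained streamingly — each batch is
    first screened against the current front, so memory is bounded by the
    front size plus one batch, never by ``n_datasets``.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be at least 1")
    rng = np.random.default_rng(seed)
    sign = _minimized(np.ones(spec.n_objectives), spec.orientations)

    front_vals: np.ndarray | None = None  # minimized orientation
    front_counts: np.ndarray | None = None
    remaining = n_datasets
    while remaining > 0:
        b = min(batch_size, remaining)
        remaining -= b
        counts = init_counts(b, n_subjects, spec.n_snps, rng)
        vals = evaluate_counts(counts, spec) * sign
        # merge in modest chunks: the pairwise non-dominance check is
        # quadratic, and after the first chunks the front screen removes
        # almost every candidate anyway
        for lo in range(0, b, merge_chunk):
            cv = vals[lo : lo + merge_chunk]
            cc = counts[lo : lo + merge_chunk]
            if front_vals is not None:
                le = (front_vals[:, None, :] <= cv[None, :, :]).all(axis=-1)
                lt = (front_vals[:, None, :] < cv[None, :, :]).any(axis=-1)
                alive = ~(le & lt).any(axis=0)
                cv, cc = cv[alive], cc[alive]
                if len(cv) == 0:
                    continue
                cv = np.concatenate([front_vals, cv])
                cc = np.concatenate([front_counts, cc])
            mask = _nondominated_mask(cv)
            front_vals, front_counts = cv[mask], cc[mask]

    values = front_vals * sign
    front = ParetoFront(values, spec.orientations, front_counts)
    rep = representative(front, normalize=spec.hwe)
    return RandomSearchResult(
        front=front,
        representative_index=rep,
        n_datasets=n_datasets,
        seed=seed,
        spec=spec,
    )
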