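# Methods

## The model

`epiforge` evolves *datasets*, not models. The individual of the evolution
strategy is a balanced case-control cohort: `n` subjects (exactly `n/2`
cases), `k` bi-allelic SNPs, genotypes in {0, 1, 2} with 1 the
heterozygote. Disease status is fixed; only genotypes evolve. Fitness is
multi-objective and purely rank-based: a dataset survives iff no other
dataset in the population is at least as good on every attribute and
strictly better on one (rank-1 Pareto selection), which lets the
population carry solutions that trade off the objectives differently and
avoids hand-weighting them into a single score.

### Attributes (objectives)

For a SNP subset *S*, the MDR accuracy marginalizes the cohort onto the
`3^|S|` genotype combinations, labels each combination high-risk when
cases outnumber controls, and scores the fraction of subjects classified
correctly. For balanced data this equals

    acc(S) = 1/2 + Σ_c |cases_c − controls_c| / (2n),

bounded by 0.5 (all cells balanced) and 1 (all cells pure). Tied and
empty cells can be labeled either way without changing the value; we label
them low-risk. Accuracy is symmetric in the class labels and monotone
under subset refinement (splitting a cell can only increase the sum of
cell maxima), so the full-order accuracy is always the largest.

A dataset's attribute vector contains, in order: `max_S acc(S)` over all
subsets of each *minimized* order (typically 1 and 2, or 1..k−1);
`acc({1..k})`, maximized; and optionally a Hardy-Weinberg disequilibrium
statistic, minimized.

### The HWE attribute

For SNP *j* with pooled (cases + controls) genotype counts
`(n0, n1, n2)`, the allele frequency is `p = (2 n0 + n1) / 2n` and the
chi-square statistic compares observed counts to `(n p², 2 n p q, n q²)`.
A monomorphic SNP scores 0 (no deviation is measurable) and is logged.
Two aggregation choices are genuinely open and exposed as options:

- across SNPs: **maximum** per-SNP chi-square (default; the dataset is only
  as QC-clean as its worst SNP, which is what per-SNP HWE filters act on)
  or the sum;
- which subjects: **pooled** cases + controls (default; conventional for
  QC) or controls only.

### Selection, capping, replication

Every generation the non-dominated set of the 1000-member population
survives and parents the next generation. When a run optimizes more than
three objectives (four/five-locus runs minimizing all lower orders, and
any HWE-constrained run) the front inflates with the extra dimension, so
survivors are capped at the 100 *elbow* members: after min-max normalizing
each objective over the front (best = 0), the 100 members closest to the
ideal point (the origin) are kept. This prefers datasets good in several
objectives over single-objective extremes. An NSGA-II crowding-distance
variant is available (`cap_method="crowding"`), and the cap threshold of
100 divides the population size so every parent gets an equal share of
offspring. Survivors are carried unchanged (elitism) and their cached
attribute values are reused; offspring are mutated copies of the parents
assigned round-robin in stable front order, so each parent leaves
`⌊(1000 − f)/f⌋` or one more offspring.

Mutation flips each of the `n·k` genotype entries independently with
probability equal to the mutation rate; a flipped entry takes one of the
two *other* states uniformly. (The alternative reading — resample from all
three states, which silently lowers the realized change rate to 2/3 of
nominal — is available as `resample_same=True` for sensitivity checks.)

After the final generation the run reports the complete non-dominated set
of the last population (the cap applies only to parent selection) and its
*representative*: the member with the smallest Euclidean distance to the
vector of per-objective optima attained on the front. When all objectives
are accuracies they share the [0.5, 1] scale and raw distances are used;
when the unbounded chi-square participates, objectives are min-max
normalized over the front first so it cannot swamp the distance. Ties
break by stable order.

## Internal representation

All scoring depends on the data only through the per-class counts over the
`3^k` genotype cells, and subjects within a cell are exchangeable, so the
contingency table is the canonical in-memory form; genotype matrices are
materialized only for file export (in a canonical order: cases before
controls, each sorted by cell index). Batch evaluation marginalizes a
single case-minus-control differential table per subset and uses
`Σ max(a,b) = (n + Σ|a−b|)/2`; the division is arranged as the single
integer ratio `(n + s)/(2n)` so batch and per-table paths produce
bit-identical floats. Table-form mutation draws the number of events from
Binomial(`n·k`, rate) and applies them sequentially — class uniform
(classes are equal-sized), cell proportional to current class counts, SNP
uniform, new state uniform over the other two — which is distributionally
identical to matrix mutation; the test suite checks this with two-sample
KS tests on attribute distributions. Non-dominance is computed on
deduplicated attribute vectors by a sum-sorted sweep (a dominator always
has a strictly smaller coordinate sum, and screening against the running
non-dominated archive suffices by transitivity), verified against the
quadratic definition-based oracle.

Randomness derives from a single per-run seed: the top-level
`SeedSequence` is split into one child stream for initialization and one
per generation, making runs reproducible bit-for-bit regardless of
internal batching. The seed and the resolved configuration are echoed in
each run's `run.json`.

## Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| subjects `n` | 3000 | full-scale runs; any even `n` accepted |
| population size | 1000 | samples the front adequately at feasible cost |
| generations | 2000 | low-order suppression saturates within a few hundred generations; full-order accuracy still improves at 2000 with diminishing returns |
| mutation rate | 0.001 at `n`=3000 | rate sweeps favour 0.004 at 500 and 0.002 at 1000 subjects; the inverse-with-`n` trend extrapolates to 0.001 at 3000. Auto-scaled unless set |
| front cap | 100 iff > 3 objectives | caps front inflation in 4-/5-objective runs; divides the population size evenly |
| initialization MAF | 0.5 | genotypes drawn at Hardy-Weinberg proportions (0.25, 0.5, 0.25); selection may drift frequencies afterwards and no re-normalization is applied |

The random-search baseline draws each class's cell counts directly from a
Multinomial(`n/2`, HWE cell probabilities) — exactly the distribution of
tabulating an i.i.d. genotype matrix (KS-tested) and vastly cheaper at two
million datasets — and maintains the non-dominated set streamingly, so
memory is bounded by the front, not the sample.

## What the generator emulates — and what it does not

Initialization emulates genotyping `n` unrelated subjects at `k`
independent, common (MAF 0.5), HWE-proportioned SNPs with no
genotype-disease association; evolution then sculpts the joint
case/control distribution. Real association data differ in ways these
datasets deliberately ignore: realistic allele-frequency spectra, linkage
disequilibrium between markers, missing genotypes, genotyping error,
covariates and unbalanced designs. Passing tests therefore demonstrate
the optimizer's behaviour on clean, balanced, LD-free cohorts —
deliberately hard *etiologies*, not realistic *genotyping*. Evolved SNPs
are intended to be embedded among noise SNPs by downstream users.

## Statistical comparison

Evolved and random-search runs are compared through their representatives'
attribute vectors with the two-sample Hotelling T², using the pooled
covariance and the exact T²-to-F conversion
`F = T² (n₁+n₂−d−1) / (d (n₁+n₂−2))`. All attributes of the
representative enter the test. A singular pooled covariance (e.g. an
attribute constant across every run) raises rather than silently
pseudo-inverting. A one-sample variant is provided.

## Numerical and design notes

- Attribute values are exact integer ratios over `2n`; dominance
  comparisons are therefore exact, with no tolerance.
- Equal attribute vectors never dominate one another, and duplicate
  vectors on a front are all retained — they are distinct datasets.
- `cap_front` and `representative` tie-breaks use stable input order, so
  results are order-deterministic.
- Generation-0-only runs (`generations=0`) report the front of the random
  initial population; a mutation rate of 0 reduces evolution to cloning
  and cannot improve on generation 0 (tested).
- The rate-sweep harness scores each rate by the representative's
  full-order accuracy on the whole dataset. No train/test split exists
  anywhere in the method, so "testing accuracy" is read as whole-dataset
  accuracy.

## Known limitations

- **The HWE-constrained configurations over-perform the published
  summaries.** The exact construction of the published HWE attribute
  (per-SNP vs. per-dataset granularity, pooling, and the elbow tie-break)
  is not recoverable, and four plausible constructions were evaluated at
  full scale: max per-SNP pooled chi-square (this package's default,
  three-way accuracy ≈ 0.78–0.84 across seeds), the same with raw-scale
  cap/representative distances (≈ 0.82), one chi-square objective per SNP
  (≈ 0.78), and a joint 27-cell chi-square against product-HWE
  expectations (≈ 0.75). All exceed the ≈ 0.68 summary value while
  driving the chi-square itself to near zero, i.e. each candidate
  construction optimizes the constrained problem more effectively than
  the original implementation did. The default is kept and the
  discrepancy is surfaced by the acceptance suite rather than hidden.
- The elbow cap is an operationalization ("smallest normalized distance
  to the ideal point") of a procedure that is described only by intent;
  the crowding-distance alternative is provided for sensitivity analysis.
- Replication is mutation-only by design; recombination operators would
  require defensible building blocks (subjects? SNPs?) and are out of
  scope.
- Problem sizes in the test and acceptance suites: full-scale experiments
  use 3 replicate seeds; the evolved-vs-random Hotelling comparison uses
  20 + 20 runs at 500 subjects / 300 generations / population 200, where
  the effect (≈ 0.75 vs ≈ 0.55 full-order accuracy) is already enormous.
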