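"""Reading and writing datasets and run outputs.

Datasets use the MDR flat-file convention: a tab-delimited text file with a
header ``X1 .. Xk Class``, one row per subject, genotypes coded 0/1/2 and
the final class column coded 1 for cases and 0 for controls — the format
downstream MDR tooling consumes directly.  Each run directory additionally
holds a ``front_info.tsv`` describing every front member, a machine-readable
``run.json`` config echo, and the per-generation ``history.tsv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ContingencyTable, GenotypeDataset, to_contingency
from .pareto import ParetoFront

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_front_info",
    "write_run_result",
]


def _canonical(dataset: GenotypeDataset | ContingencyTable) -> GenotypeDataset:
    table = (
        dataset
        if isinstance(dataset, ContingencyTable)
        else to_contingency(dataset)
    )
    return table.to_dataset()


def write_dataset(
    dataset: GenotypeDataset | ContingencyTable, destination
) -> None:
    """Write a dataset as an MDR flat file.

    Subject order is canonical — cases before controls, each class sorted
    by genotype-cell index — because the contingency representation carries
    no subject identity.  Accepts either representation.
    """
    d = _canonical(dataset)
    path = Path(destination)
    header = "\t".join([f"X{j + 1}" for j in range(d.n_snps)] + ["Class"])
    body = np.column_stack([d.genotypes, d.status])
    try:
        with path.open("w") as fh:
            fh.write(header + "\n")
            for row in body:
                fh.write("\t".join(map(str, row)) + "\n")
    except OSError as exc:
        raise OSError(f"could not write dataset to {path}: {exc}") from exc


class DatasetFormatError(ValueError):
    """A dataset file violates the MDR flat-file dialect."""


def read_dataset(source, lenient: bool = False) -> GenotypeDataset:
    """Read an MDR flat file back into a validated dataset.

    The strict dialect requires tab separation and the exact header
    ``X1 .. Xk`` followed by ``Class``.  With ``lenient=True`` the columns
    may appear in any order (they are matched by name).  Malformed
    genotypes, a missing header or unbalanced classes are rejected with the
    offending line number.
    """
    path = Path(source)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DatasetFormatError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    if "Class" not in header:
        raise DatasetFormatError(
            f"{path}: line 1: header must contain a 'Class' column, got {header!r}"
        )
    k = len(header) - 1
    expected = [f"X{j + 1}" for j in range(k)] + ["Class"]
    if header != expected:
        if not lenient:
            raise DatasetFormatError(
                f"{path}: line 1: strict dialect expects header {expected!r}, "
                f"got {header!r} (pass lenient=True to match columns by name)"
            )
        if sorted(header) != sorted(expected):
            raise DatasetFormatError(
                f"{path}: line 1: header must consist of {expected!r} in some "
                f"order, got {header!r}"
            )
    order = [header.index(name) for name in expected]
    genotypes, status = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != k + 1:
            raise DatasetFormatError(
                f"{path}: line {lineno}: expected {k + 1} fields, got {len(fields)}"
            )
        fields = [fields[i] for i in order]
        try:
            row = [int(v) for v in fields]
        except ValueError:
            raise DatasetFormatError(
                f"{path}: line {lineno}: non-integer entry in {fields!r}"
            ) from None
        if any(g not in (0, 1, 2) for g in row[:k]):
            raise DatasetFormatError(
                f"{path}: line {lineno}: genotypes must be 0, 1 or 2, got {row[:k]}"
            )
        if row[k] not in (0, 1):
            raise DatasetFormatError(
                f"{path}: line {lineno}: class must be 0 or 1, got {row[k]}"
            )
        genotypes.append(row[:k])
        status.append(row[k])
    if not genotypes:
        raise DatasetFormatError(f"{path}: no subject rows")
    try:
        return GenotypeDataset(np.array(genotypes), np.array(status))
    except ValueError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc


def front_info_frame(
    front: ParetoFront,
    labels,
    representative_index: int,
    filenames=None,
) -> pd.DataFrame:
    """Tabulate a front: one row per member with every attribute value."""
    info = pd.DataFrame(front.values, columns=list(labels))
    info.insert(0, "member", np.arange(len(front)))
    info["representative"] = 0
    info.loc[representative_index, "representative"] = 1
    if filenames is not None:
        info.insert(1, "dataset_file", list(filenames))
    return info


def write_front_info(
    front: ParetoFront,
    labels,
    representative_index: int,
    destination,
    filenames=None,
) -> None:
    """Write the per-member front description as a TSV.

    One record per front member: optional dataset filename, every attribute
    (per-order accuracies and the HWE statistic when active) and a flag
    marking the run's representative — enough to filter archives for, e.g.,
    fronts whose one- and two-way accuracies stay below 52%.
    """
    info = front_info_frame(front, labels, representative_index, filenames)
    info.to_csv(destination, sep="\t", index=False, float_format="%.10g")


def write_run_result(result, out_dir, save_front: bool = False) -> Path:
    """Write a completed run (evolution or random search) to a directory.

    Always saves the representative dataset (``representative.txt``),
    ``front_info.tsv`` and ``run.json``; with ``save_front=True`` every
    front member is exported as ``front/dataset_NNN.txt``.  Evolution runs
    additionally store the per-generation ``history.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    front = result.front if hasattr(result, "front") else result.final_front
    rep = result.representative_index

    config = getattr(result, "config", None)
    if config is not None:
        spec = config.objective_spec
        meta = {"config": config.to_dict(), "seed": config.seed}
    else:  # random search
        spec = result.spec
        meta = {
            "n_datasets": result.n_datasets,
            "seed": result.seed,
            "objectives": list(spec.labels),
        }
    labels = spec.labels

    write_dataset(front.member_table(rep), out / "representative.txt")
    filenames = None
    if save_front:
        front_dir = out / "front"
        front_dir.mkdir(exist_ok=True)
        filenames = [f"front/dataset_{i:04d}.txt" for i in range(len(front))]
        for i, name in enumerate(filenames):
            write_dataset(front.member_table(i), out / name)
    write_front_info(front, labels, rep, out / "front_info.tsv", filenames)

    history = getattr(result, "history", None)
    if history is not None:
        history.to_csv(out / "history.tsv", sep="\t", index=False)
    meta["representative_index"] = int(rep)
    meta["front_size"] = len(front)
    meta["representative_values"] = [float(v) for v in front.values[rep]]
    with (out / "run.json").open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
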