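"""Delimited expression-matrix readers and writers.

Source series are assumed pre-exported as plain TSV/CSV numeric matrices
with row and column identifiers; an orientation flag handles the common
genes-as-rows layout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datasets import ExpressionDataset

ORIENTATIONS = ("samples_by_variables", "variables_by_samples")


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(f"{path}: could not detect a tab or comma delimiter")


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_by_variables",
    provenance: str | None = None,
) -> ExpressionDataset:
    """Load a delimited numeric matrix (first column = row ids).

    ``orientation='variables_by_samples'`` transposes a genes-as-rows file
    into the samples x variables layout used throughout.  Missing or
    non-numeric cells and duplicate identifiers raise with the offending
    coordinates.
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    sep = _detect_sep(path)
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header_ids)) != len(header_ids):
        seen, dupes = set(), []
        for h in header_ids:
            if h in seen:
                dupes.append(h)
            seen.add(h)
        raise ValueError(f"{path}: duplicate column ids {sorted(set(dupes))[:5]}")
    frame = pd.read_csv(
        path, sep=sep, index_col=0, float_precision="round_trip"
    )
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate row ids {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate column ids {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = bad.to_numpy().nonzero()
        i, j = rows[0], cols[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row "
            f"{frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if orientation == "variables_by_samples":
        numeric = numeric.T
    return ExpressionDataset.from_frame(
        numeric, provenance=provenance if provenance is not None else str(path)
    )


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write samples x variables as TSV (or CSV when the suffix is .csv)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    dataset.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def read_dataset_dir(
    directory: str | Path, orientation: str = "samples_by_variables"
) -> dict[str, ExpressionDataset]:
    """Load every .tsv/.csv matrix in a directory, keyed by file stem."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"dataset directory {directory} does not exist")
    datasets = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in {".tsv", ".csv"} and not path.name.endswith(
            ".truth.json"
        ):
            datasets[path.stem] = read_expression_matrix(path, orientation)
    if not datasets:
        raise FileNotFoundError(f"no .tsv/.csv matrices in {directory}")
    return datasets
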