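"""Plain-text file formats: COO tensors, factor CSVs, label TSVs.

The tensor dialect is one line per nonzero — N integer index columns
followed by a positive integer count — tab-delimited and 0-based by
default (1-based accepted via the dialect). Factor matrices round-trip as
one CSV per mode plus a weights CSV.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor import KruskalModel, SparseCountTensor

__all__ = [
    "CooDialect",
    "read_coo",
    "write_coo",
    "write_factors",
    "read_factors",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class CooDialect:
    """Delimiter, index base (0 or 1), and header flag of a COO text file."""

    delimiter: str = "\t"
    index_base: int = 0
    header: bool = False

    def __post_init__(self) -> None:
        if self.index_base not in (0, 1):
            raise ValueError("index_base must be 0 or 1")


def read_coo(path, dialect: CooDialect = CooDialect(), shape=None) -> SparseCountTensor:
    """Read a coordinate-format count tensor.

    The mode count is inferred from the column count (last column is the
    value). Duplicate coordinates are summed with a warning. Malformed
    lines raise a parse error naming the line number. When ``shape`` is
    omitted it is inferred as 1 + the per-mode maximum index.
    """
    rows: list[list[int]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and dialect.header:
                continue
            line = line.strip()
            if not line:
                continue
            parts = line.split(dialect.delimiter)
            if width is None:
                width = len(parts)
                if width < 4:
                    raise ValueError(
                        f"{path}:{lineno}: need at least 3 index columns plus a value"
                    )
            elif len(parts) != width:
                raise ValueError(
                    f"{path}:{lineno}: expected {width} columns, got {len(parts)}"
                )
            try:
                vals = [int(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            idx = [v - dialect.index_base for v in vals[:-1]]
            if any(i < 0 for i in idx):
                raise ValueError(f"{path}:{lineno}: negative index after rebasing")
            if vals[-1] <= 0:
                raise ValueError(f"{path}:{lineno}: value must be a positive integer")
            rows.append(idx + [vals[-1]])
    if not rows:
        if shape is None:
            raise ValueError(f"{path}: empty file and no shape declared")
        return SparseCountTensor(
            tuple(shape), np.empty((0, len(shape)), dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
    arr = np.asarray(rows, dtype=np.int64)
    idx, val = arr[:, :-1], arr[:, -1]
    uniq = np.unique(idx, axis=0)
    if uniq.shape[0] != idx.shape[0]:
        warnings.warn(
            f"{path}: {idx.shape[0] - uniq.shape[0]} duplicate coordinate(s) summed",
            RuntimeWarning,
            stacklevel=2,
        )
    return SparseCountTensor.from_entries(idx, val, shape=shape, sum_duplicates=True)


def write_coo(X: SparseCountTensor, path, dialect: CooDialect = CooDialect()) -> None:
    """Write a tensor in the coordinate dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        if dialect.header:
            cols = [f"i{n}" for n in range(X.ndim)] + ["value"]
            fh.write(dialect.delimiter.join(cols) + "\n")
        for idx, v in zip(X.indices, X.values):
            fields = [str(int(i) + dialect.index_base) for i in idx] + [str(int(v))]
            fh.write(dialect.delimiter.join(fields) + "\n")


def write_factors(model: KruskalModel, directory) -> None:
    """One CSV per mode (index column + r0..r{R-1}) plus weights.csv."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    for n, A in enumerate(model.factors):
        df = pd.DataFrame(A, columns=[f"r{r}" for r in range(model.rank)])
        df.insert(0, "index", np.arange(A.shape[0]))
        df.to_csv(directory / f"mode{n}.csv", index=False, float_format="%.17g")
    pd.DataFrame({"weight": model.weights}).to_csv(
        directory / "weights.csv", index=False, float_format="%.17g"
    )


def read_factors(directory) -> KruskalModel:
    """Reload a model written by :func:`write_factors`."""
    directory = Path(directory)
    weights = pd.read_csv(directory / "weights.csv")["weight"].to_numpy()
    factors = []
    n = 0
    while (directory / f"mode{n}.csv").exists():
        df = pd.read_csv(directory / f"mode{n}.csv")
        factors.append(df.drop(columns=["index"]).to_numpy(dtype=np.float64))
        n += 1
    if not factors:
        raise FileNotFoundError(f"no mode*.csv files under {directory}")
    return KruskalModel(weights, factors)


def read_labels(path) -> dict[int, int]:
    """Read a (entity-index, 0/1) TSV into a label map."""
    labels: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                i, y = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer field") from None
            if y not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {y}")
            labels[i] = y
    return labels


def write_labels(labels, path) -> None:
    """Write a label map (or array with -1 = unlabeled) as a 2-column TSV."""
    with open(path, "w") as fh:
        if isinstance(labels, dict):
            items = sorted(labels.items())
        else:
            arr = np.asarray(labels)
            items = [(i, int(y)) for i, y in enumerate(arr) if y >= 0]
        for i, y in items:
            fh.write(f"{i}\t{y}\n")
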