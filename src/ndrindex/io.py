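"""Readers and writers for the formats the tool touches.

Dense matrices travel as CSV/TSV with cell ids in the first column and gene
ids in the header; sparse matrices as Matrix Market ``.mtx`` with one-id-
per-line sidecar files (``<path>.rows`` for cells, ``<path>.cols`` for
genes).  Cells are rows everywhere internally; genes-x-cells files are
accepted via ``transpose=True``.  Labels are two-column CSV
``cell_id,label``.  Report files start with ``#``-prefixed reproducibility
header lines carrying the config and seed used.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .core import InvalidInputError
from .preprocess import ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_config",
    "write_report_csv",
    "write_report_json",
]

_FORMATS = ("csv", "tsv", "mtx")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise InvalidInputError(
        f"cannot infer format from {path.name!r}; pass format= one of {_FORMATS}"
    )


def _check_values(values: np.ndarray, path: Path) -> None:
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise InvalidInputError(f"{path}: NaN entry at row {i}, column {j}")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise InvalidInputError(
            f"{path}: negative entry {values[i, j]} at row {i}, column {j}"
        )


def _check_ids(ids: list[str], what: str, source: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise InvalidInputError(f"{source}: duplicate {what} id {dup!r}")


def read_matrix(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV or Matrix Market.

    ``mtx`` files need ``<path>.rows`` / ``<path>.cols`` sidecars naming the
    cells and genes.  ``transpose=True`` flips a genes-x-cells file into the
    internal cells-x-genes orientation (sidecar roles flip accordingly).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        frame = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        values = frame.to_numpy(dtype=np.float64)
        row_ids = [str(i) for i in frame.index]
        col_ids = [str(c) for c in frame.columns]
    elif fmt == "mtx":
        rows_path = path.with_suffix(path.suffix + ".rows")
        cols_path = path.with_suffix(path.suffix + ".cols")
        for sidecar in (rows_path, cols_path):
            if not sidecar.exists():
                raise InvalidInputError(f"missing sidecar file: {sidecar}")
        matrix = scipy.io.mmread(path)
        values = np.asarray(
            matrix.todense() if sp.issparse(matrix) else matrix, dtype=np.float64
        )
        row_ids = rows_path.read_text().split()
        col_ids = cols_path.read_text().split()
        if len(row_ids) != values.shape[0]:
            raise InvalidInputError(
                f"sidecar {rows_path} has {len(row_ids)} ids for "
                f"{values.shape[0]} matrix rows"
            )
        if len(col_ids) != values.shape[1]:
            raise InvalidInputError(
                f"sidecar {cols_path} has {len(col_ids)} ids for "
                f"{values.shape[1]} matrix columns"
            )
    else:
        raise InvalidInputError(f"unknown format {fmt!r}; choose from {_FORMATS}")

    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    _check_values(values, path)
    _check_ids(row_ids, "cell", str(path))
    _check_ids(col_ids, "gene", str(path))
    return ExpressionMatrix(values, tuple(row_ids), tuple(col_ids))


def write_matrix(X: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write an expression matrix as CSV/TSV or Matrix Market + sidecars."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        pd.DataFrame(X.counts, index=X.cell_ids, columns=X.gene_ids).to_csv(
            path, sep="," if fmt == "csv" else "\t"
        )
    elif fmt == "mtx":
        scipy.io.mmwrite(path, sp.coo_matrix(X.counts))
        path.with_suffix(path.suffix + ".rows").write_text("\n".join(X.cell_ids) + "\n")
        path.with_suffix(path.suffix + ".cols").write_text("\n".join(X.gene_ids) + "\n")
    else:
        raise InvalidInputError(f"unknown format {fmt!r}; choose from {_FORMATS}")


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read (cell_ids, labels) from a two-column ``cell_id,label`` CSV."""
    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] != 2:
        raise InvalidInputError(
            f"{path}: expected two columns (cell_id, label), got {frame.shape[1]}"
        )
    return [str(i) for i in frame.iloc[:, 0]], frame.iloc[:, 1].to_numpy()


def write_labels(
    cell_ids: tuple[str, ...] | list[str],
    labels: np.ndarray,
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("cell_id,label\n")
        for cid, lab in zip(cell_ids, labels):
            fh.write(f"{cid},{lab}\n")


def read_config(path: str | Path) -> dict:
    """Plain-text key-value (YAML subset) run configuration."""
    with Path(path).open() as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise InvalidInputError(f"{path}: config must be a key-value mapping")
    return config


def write_report_csv(
    frame: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a tidy report with ``#`` reproducibility header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def write_report_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
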