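"""Reading and writing delimited expression matrices and label files."""

from __future__ import annotations

import pandas as pd

from .dataset import ExpressionDataset

_NA_STRINGS = {"", "NA", "N/A", "NaN", "nan", "NULL", "null"}


def _check_duplicate_header(path, delimiter: str) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    ids = header[1:]
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate id in header: {name!r}")
        seen.add(name)


def read_expression_matrix(
    path, delimiter: str = "\t", genes_in_rows: bool = True
) -> ExpressionDataset:
    """Read a delimited expression matrix into an :class:`ExpressionDataset`.

    The first row holds sample ids (or gene ids when ``genes_in_rows`` is
    False) and the first column holds the other axis' ids. Non-numeric cells
    are hard errors reported with their row/column ids; cells that are
    conventional NA strings become missing values (the dataset constructor
    then drops incomplete gene rows with a warning).
    """
    _check_duplicate_header(path, delimiter)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() & ~raw.isin(_NA_STRINGS)
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    if not genes_in_rows:
        numeric = numeric.T
    numeric.index = numeric.index.astype(str).rename(None)
    numeric.columns = numeric.columns.astype(str).rename(None)
    return ExpressionDataset(numeric)


def write_expression_matrix(ds: ExpressionDataset, path, delimiter: str = "\t") -> None:
    ds.values.to_csv(path, sep=delimiter, index_label="gene_id")


def read_labels(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, condition) label file."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, condition")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in labels: {dup!r}")
    return ser


def write_labels(condition: pd.Series, path, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": condition.index, "condition": condition.values}).to_csv(
        path, sep=delimiter, index=False
    )
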