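"""Core container: a genes x samples expression matrix with sample labels."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _first_duplicate(index: pd.Index) -> object:
    return index[index.duplicated()][0]


class ExpressionDataset:
    """Log-scale expression values (genes in rows, samples in columns).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Rows
        containing missing values are dropped (with a warning): downstream
        correlation and PCA steps require complete rows.
    condition
        Optional per-sample categorical label (Series indexed by sample
        id). Every sample must be labelled when labels are attached;
        downstream classification steps require exactly two levels.
    """

    def __init__(self, values: pd.DataFrame, condition: pd.Series | None = None):
        if values.index.has_duplicates:
            raise ValueError(f"duplicate gene id: {_first_duplicate(values.index)!r}")
        if values.columns.has_duplicates:
            raise ValueError(
                f"duplicate sample id: {_first_duplicate(values.columns)!r}"
            )
        vals = values.astype(float)
        incomplete = vals.isna().any(axis=1)
        if incomplete.any():
            warnings.warn(
                f"dropping {int(incomplete.sum())} gene row(s) with missing values",
                stacklevel=2,
            )
            vals = vals.loc[~incomplete]
        self.values = vals
        if condition is not None:
            condition = pd.Series(condition)
            unlabeled = vals.columns.difference(condition.index)
            if len(unlabeled) > 0:
                raise ValueError(f"samples without condition label: {list(unlabeled)}")
            condition = condition.reindex(vals.columns)
        self.condition = condition

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def conditions(self) -> list:
        """Distinct condition labels in sorted order."""
        if self.condition is None:
            raise ValueError("dataset has no condition labels")
        return sorted(self.condition.unique())

    def samples_in_condition(self, label) -> list[str]:
        if self.condition is None:
            raise ValueError("dataset has no condition labels")
        return list(self.condition.index[self.condition == label])

    # -- derivation ----------------------------------------------------------

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        return ExpressionDataset(self.values.loc[list(gene_ids)], self.condition)

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in dataset: {missing[:5]}")
        cond = self.condition.loc[list(sample_ids)] if self.condition is not None else None
        return ExpressionDataset(self.values[list(sample_ids)], cond)

    def with_condition(self, condition: pd.Series) -> "ExpressionDataset":
        return ExpressionDataset(self.values, condition)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = "labelled" if self.condition is not None else "unlabelled"
        return f"ExpressionDataset({self.n_genes} genes x {self.n_samples} samples, {lab})"
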