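"""Expression preprocessing: log transform and differential-expression filter.

Genes with little evidence of differential expression between the two
conditions are removed before network construction; by default the top third
of genes ranked by Welch p-value is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import stats as _stats
from .dataset import ExpressionDataset


@dataclass
class GeneStat:
    """Per-gene Welch test result (Bonferroni-adjusted over all genes tested)."""

    gene_id: str
    t: float
    df: float
    p: float
    p_adj: float


def log_transform_rpkm(ds: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Natural-log transform raw abundance values: ``v -> ln(v + pseudocount)``."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = ds.values.to_numpy()
    shifted = vals + pseudocount
    if np.any(shifted <= 0):
        raise ValueError("log transform undefined: value + pseudocount <= 0 found")
    return ExpressionDataset(np.log(ds.values + pseudocount), ds.condition)


def welch_t_per_gene(ds: ExpressionDataset, cond_a, cond_b) -> list[GeneStat]:
    """Welch's t-test for every gene between two conditions.

    p-values are Bonferroni-adjusted over all genes tested.
    """
    a_samples = ds.samples_in_condition(cond_a)
    b_samples = ds.samples_in_condition(cond_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each condition needs at least 2 samples")
    A = ds.values[a_samples].to_numpy()
    B = ds.values[b_samples].to_numpy()
    out = []
    for i, gene in enumerate(ds.gene_ids):
        t, df, p = _stats.welch_t(A[i], B[i])
        out.append(GeneStat(gene, t, df, p, p))
    adj = _stats.bonferroni([g.p for g in out])
    for g, a in zip(out, adj):
        g.p_adj = float(a)
    return out


def filter_top_fraction(
    ds: ExpressionDataset, gene_stats: list[GeneStat], fraction: float
) -> ExpressionDataset:
    """Keep the ``ceil(fraction * n_genes)`` genes with smallest raw p-value.

    Ties on p are broken by larger ``|t|``, then lexicographic gene id.
    Gene order of the surviving genes follows the input dataset.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    by_gene = {g.gene_id: g for g in gene_stats}
    missing = [g for g in ds.gene_ids if g not in by_gene]
    if missing:
        raise ValueError(f"stats missing for genes: {missing[:5]}")
    k = math.ceil(fraction * ds.n_genes)
    ranked = sorted(
        ds.gene_ids, key=lambda g: (by_gene[g].p, -abs(by_gene[g].t), g)
    )
    keep = set(ranked[:k])
    return ds.subset_genes([g for g in ds.gene_ids if g in keep])
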