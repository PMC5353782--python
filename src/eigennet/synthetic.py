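"""Synthetic expression data with planted coexpression modules.

Each module is driven by one latent factor per sample; module genes load on
their factor with loadings drawn uniformly from a configurable range plus
independent Gaussian noise, so the module's first principal component is
the correct summary and parameter recovery is well defined. The latent
factor mean differs between the two conditions by a per-module effect size
(in latent-sd units), planting condition-dependent modules. Background
genes are pure unit-variance noise and should remain unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give 5 modules / 600 genes / 240 samples."""

    module_sizes: tuple = (100, 100, 100, 90, 90)
    n_background_genes: int = 120
    samples_per_condition: tuple = (120, 120)
    effect_sizes: tuple = (3.0, 2.0, 0.0, 0.0, 0.0)
    loading_range: tuple = (0.6, 0.95)
    noise_sd: float = 0.5
    condition_labels: tuple = ("A", "B")
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if len(self.effect_sizes) != self.n_modules:
            raise ValueError("one effect size per module required")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading range must satisfy 0 < low <= high <= 1")
        if any(n < 2 for n in self.samples_per_condition):
            raise ValueError("each condition needs at least 2 samples")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    module_labels: pd.Series  # gene id -> planted module (0 = background)
    latent: pd.DataFrame  # samples x modules factor values
    loadings: pd.Series  # gene id -> loading (0 for background)


def generate_modular_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw one dataset from the planted-module generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.samples_per_condition
    lab_a, lab_b = spec.condition_labels
    n_samples = n_a + n_b
    sample_ids = [f"{lab_a}{i + 1:03d}" for i in range(n_a)] + [
        f"{lab_b}{i + 1:03d}" for i in range(n_b)
    ]
    condition = pd.Series([lab_a] * n_a + [lab_b] * n_b, index=sample_ids)

    gene_ids: list[str] = []
    module_labels: list[int] = []
    rows: list[np.ndarray] = []
    loadings: list[float] = []
    latent = {}
    for m, (size, effect) in enumerate(zip(spec.module_sizes, spec.effect_sizes), 1):
        mu = np.where(np.arange(n_samples) < n_a, effect / 2.0, -effect / 2.0)
        f = rng.normal(mu, 1.0)
        latent[m] = f
        lam = rng.uniform(*spec.loading_range, size=size)
        noise = rng.normal(0.0, spec.noise_sd, size=(size, n_samples))
        rows.append(lam[:, None] * f[None, :] + noise)
        gene_ids.extend(f"M{m:02d}G{j + 1:03d}" for j in range(size))
        module_labels.extend([m] * size)
        loadings.extend(lam)
    if spec.n_background_genes:
        rows.append(rng.normal(0.0, 1.0, size=(spec.n_background_genes, n_samples)))
        gene_ids.extend(f"BG{j + 1:04d}" for j in range(spec.n_background_genes))
        module_labels.extend([0] * spec.n_background_genes)
        loadings.extend([0.0] * spec.n_background_genes)

    values = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)
    ds = ExpressionDataset(values, condition)
    truth = SyntheticTruth(
        pd.Series(module_labels, index=gene_ids),
        pd.DataFrame(latent, index=sample_ids),
        pd.Series(loadings, index=gene_ids),
    )
    return ds, truth


def split_train_test(
    ds: ExpressionDataset, test_fraction: float, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Disjoint stratified train/test split of the samples."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if ds.condition is None:
        raise ValueError("stratified split requires condition labels")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in ds.conditions():
        members = ds.samples_in_condition(c)
        n_test = int(round(test_fraction * len(members)))
        if n_test < 2 or len(members) - n_test < 2:
            raise ValueError(
                f"condition {c!r}: split leaves fewer than 2 samples on one side"
            )
        perm = rng.permutation(len(members))
        test_ids.extend(members[i] for i in perm[:n_test])
        train_ids.extend(members[i] for i in perm[n_test:])
    order = {s: i for i, s in enumerate(ds.sample_ids)}
    train_ids.sort(key=order.get)
    test_ids.sort(key=order.get)
    return ds.subset_samples(train_ids), ds.subset_samples(test_ids)
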