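"""Module eigengenes: class-balanced PCA summaries and cross-dataset projection.

An eigengene is the first principal component of a module's scaled
(per-gene z-scored) expression, i.e. a weighted average of member-gene
expression with unit-norm weights chosen to maximize explained variance.
Weights are learned once on a (class-balanced) training dataset and frozen;
in an independent dataset the eigengene is inferred by applying the frozen
weights to that dataset's own z-scaled expression of the shared genes, which
makes eigengene values comparable across profiling platforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import ModuleAssignment
from .dataset import ExpressionDataset


@dataclass
class ModuleEigengene:
    """Frozen per-module summary: member genes, unit-norm weights, orientation."""

    genes: list[str]
    weights: np.ndarray
    orientation_sign: int = 1
    explained_variance: float = float("nan")


@dataclass
class EigengeneModel:
    """Per-module eigengene weight vectors learned on a training dataset."""

    modules: dict[int, ModuleEigengene]
    metadata: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.modules)

    def genes(self) -> list[str]:
        """All member genes across modules (unique, insertion order)."""
        seen: dict[str, None] = {}
        for m in self.module_ids:
            for g in self.modules[m].genes:
                seen.setdefault(g)
        return list(seen)

    def to_json(self, path) -> None:
        payload = {
            "modules": {
                str(m): {
                    "genes": me.genes,
                    "weights": [float(w) for w in me.weights],
                    "orientation_sign": me.orientation_sign,
                    "explained_variance": me.explained_variance,
                }
                for m, me in self.modules.items()
            },
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EigengeneModel":
        with open(path) as fh:
            payload = json.load(fh)
        modules = {
            int(m): ModuleEigengene(
                d["genes"],
                np.asarray(d["weights"], dtype=float),
                int(d.get("orientation_sign", 1)),
                float(d.get("explained_variance", float("nan"))),
            )
            for m, d in payload["modules"].items()
        }
        return cls(modules, payload.get("metadata", {}))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def balance_by_oversampling(
    ds: ExpressionDataset, target="auto"
) -> tuple[ExpressionDataset, dict]:
    """Replicate samples so both classes contribute comparably.

    Each sample of condition ``c`` with ``n_c`` samples is repeated
    ``r_c = max(1, round(target / n_c))`` times (round half up). ``"auto"``
    sets ``target = 9 * max(n_c)``. Replicated sample ids get a ``.repK``
    suffix. Returns the oversampled dataset and the per-condition factors.
    """
    conds = ds.conditions()
    if len(conds) != 2:
        raise ValueError(f"exactly 2 condition labels required, got {conds}")
    counts = {c: len(ds.samples_in_condition(c)) for c in conds}
    if min(counts.values()) == 0:
        raise ValueError("a condition has no samples")
    if target == "auto":
        target = 9 * max(counts.values())
    if target < 1:
        raise ValueError("target must be positive")
    factors = {c: max(1, _round_half_up(target / counts[c])) for c in conds}
    cols, labels, new_ids = [], [], []
    for s in ds.sample_ids:
        c = ds.condition.loc[s]
        for rep in range(1, factors[c] + 1):
            cols.append(s)
            new_ids.append(f"{s}.rep{rep}")
            labels.append(c)
    values = ds.values[cols].copy()
    values.columns = new_ids
    cond = pd.Series(labels, index=new_ids)
    return ExpressionDataset(values, cond), factors


def _zscore_columns(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each gene row; returns scaled frame and zero-variance genes."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    degenerate = values.index[sd == 0]
    ok = values.loc[sd > 0]
    scaled = ok.sub(mean[sd > 0], axis=0).div(sd[sd > 0], axis=0)
    return scaled, degenerate


def compute_eigengenes(
    ds: ExpressionDataset,
    modules: ModuleAssignment,
    balance: bool = True,
    target="auto",
) -> tuple[EigengeneModel, pd.DataFrame]:
    """Fit eigengene weights per module and evaluate them on the dataset.

    Per module: the member genes' expression (optionally class-balanced by
    oversampling) is z-scored per gene; the unit-norm weight vector is the
    first right singular vector of the samples x genes scaled matrix, with
    its sign flipped so the eigengene correlates non-negatively with the
    members' mean scaled profile. Eigengene values are reported for the
    original samples only (each once), by projecting the frozen weights
    onto the dataset.

    Returns the frozen :class:`EigengeneModel` and a samples x modules
    eigengene value frame.
    """
    fit_ds = ds
    factors: dict = {}
    if balance:
        if ds.condition is None:
            raise ValueError("balancing requires condition labels")
        fit_ds, factors = balance_by_oversampling(ds, target)
    model_modules: dict[int, ModuleEigengene] = {}
    for m in modules.module_ids:
        members = [g for g in modules.genes_in(m) if g in fit_ds.values.index]
        if len(members) < 2:
            warnings.warn(f"module {m}: fewer than 2 member genes present; skipped")
            continue
        scaled, degenerate = _zscore_columns(fit_ds.values.loc[members])
        if len(degenerate) > 0:
            warnings.warn(
                f"module {m}: dropping zero-variance gene(s) {list(degenerate)}"
            )
        if scaled.shape[0] < 2:
            warnings.warn(f"module {m}: fewer than 2 usable genes; skipped")
            continue
        Z = scaled.to_numpy().T  # samples x genes
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        w = vt[0]
        eig = Z @ w
        mean_profile = Z.mean(axis=1)
        c = float(np.dot(eig - eig.mean(), mean_profile - mean_profile.mean()))
        sign = 1
        if c < 0:
            sign = -1
        elif c == 0 and w[np.argmax(np.abs(w))] < 0:
            sign = -1
        w = sign * w
        ev = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else float("nan")
        model_modules[m] = ModuleEigengene(list(scaled.index), w, sign, ev)
    model = EigengeneModel(
        model_modules,
        metadata={
            "balanced": bool(balance),
            "replication_factors": {str(k): int(v) for k, v in factors.items()},
            "n_training_samples": ds.n_samples,
        },
    )
    return model, project_eigengenes(model, ds)


def project_eigengenes(model: EigengeneModel, ds: ExpressionDataset) -> pd.DataFrame:
    """Infer eigengene values in a dataset using frozen training weights.

    Per module: genes common to the model and the dataset are z-scored
    within the dataset (its own means/sds); the surviving weight sub-vector
    is rescaled to unit norm; the eigengene is the weighted sum of the
    z-scored values. A module with no usable common gene yields an
    all-missing column (flagged with a warning).
    """
    out = pd.DataFrame(index=ds.sample_ids, dtype=float)
    for m in model.module_ids:
        me = model.modules[m]
        common = [g for g in me.genes if g in ds.values.index]
        if len(common) < len(me.genes):
            warnings.warn(
                f"module {m}: {len(me.genes) - len(common)} model gene(s) "
                "missing from the dataset"
            )
        if not common:
            out[m] = np.nan
            continue
        scaled, degenerate = _zscore_columns(ds.values.loc[common])
        if len(degenerate) > 0:
            warnings.warn(
                f"module {m}: dropping zero-variance gene(s) {list(degenerate)}"
            )
        usable = list(scaled.index)
        if not usable:
            out[m] = np.nan
            continue
        idx = [me.genes.index(g) for g in usable]
        w = me.weights[idx]
        norm = np.linalg.norm(w)
        if norm == 0:
            out[m] = np.nan
            continue
        w = w / norm
        col = scaled.to_numpy().T @ w
        # report on a normalized (unit-variance) scale: eigengene magnitude
        # otherwise grows with the member count, which would silently shift
        # frozen decision thresholds across datasets or under gene removal
        sd = col.std(ddof=1)
        out[m] = col / sd if sd > 0 else col
    return out
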