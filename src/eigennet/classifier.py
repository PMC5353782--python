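"""Threshold decision trees over eigengenes and greedy gene-set compaction.

The tree splits on one eigengene feature at a time, choosing the
(feature, threshold) pair with the largest information gain ratio among
midpoints of consecutive distinct values, with a per-leaf sample floor
(default 10% of the training set). Compaction repeatedly removes the gene
with the smallest absolute weight among all genes backing the tree's
feature modules, re-derives eigengenes by projection with the reduced
weights, and re-evaluates accuracy with the tree structure and thresholds
held fixed.
"""

from __future__ import annotations

import copy
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .eigengene import EigengeneModel, project_eigengenes


@dataclass
class Leaf:
    label: object
    counts: dict = field(default_factory=dict)  # class label -> training count


@dataclass
class Split:
    feature: object  # module id
    threshold: float
    left: object  # samples with value <= threshold
    right: object


@dataclass
class DecisionTree:
    root: object
    classes: list
    min_per_leaf_fraction: float = 0.10

    def features(self) -> list:
        """Module ids used by internal nodes (first-use order)."""
        out: list = []

        def walk(node):
            if isinstance(node, Split):
                if node.feature not in out:
                    out.append(node.feature)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    # -- serialization -------------------------------------------------------

    def _node_dict(self, node) -> dict:
        if isinstance(node, Leaf):
            return {"leaf": True, "label": node.label, "counts": dict(node.counts)}
        return {
            "leaf": False,
            "feature": node.feature,
            "threshold": node.threshold,
            "left": self._node_dict(node.left),
            "right": self._node_dict(node.right),
        }

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "min_per_leaf_fraction": self.min_per_leaf_fraction,
            "root": self._node_dict(self.root),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DecisionTree":
        with open(path) as fh:
            payload = json.load(fh)

        def build(d):
            if d["leaf"]:
                return Leaf(d["label"], dict(d.get("counts", {})))
            return Split(
                d["feature"], float(d["threshold"]), build(d["left"]), build(d["right"])
            )

        return cls(
            build(payload["root"]),
            payload["classes"],
            float(payload.get("min_per_leaf_fraction", 0.10)),
        )

    def render(self) -> str:
        """Indented text rendering of the decision rules."""
        lines: list[str] = []

        def walk(node, indent):
            pad = "  " * indent
            if isinstance(node, Leaf):
                lines.append(f"{pad}-> {node.label} {node.counts}")
            else:
                lines.append(f"{pad}if eigengene[{node.feature}] <= {node.threshold:g}:")
                walk(node.left, indent + 1)
                lines.append(f"{pad}else:")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def fit_tree(
    eig: pd.DataFrame,
    labels: pd.Series,
    features=None,
    min_per_leaf_fraction: float = 0.10,
) -> DecisionTree:
    """Fit a binary threshold tree on eigengene features.

    Splits maximize information gain ratio over all features and all
    midpoints between consecutive distinct values; children below the leaf
    floor ``ceil(min_per_leaf_fraction * n)`` are not considered. Recursion
    stops on pure nodes or when no split has positive gain. Leaf labels are
    the majority class (ties go to the smaller label code).
    """
    if features is None:
        features = list(eig.columns)
    missing = [f for f in features if f not in eig.columns]
    if missing:
        raise ValueError(f"features not in eigengene matrix: {missing}")
    y = labels.loc[eig.index]
    classes = sorted(y.unique())
    if len(classes) == 1:  # pure input: trivial single-leaf tree
        return DecisionTree(
            Leaf(classes[0], {classes[0]: len(y)}), classes, min_per_leaf_fraction
        )
    if len(classes) != 2:
        raise ValueError(f"2 classes required, got {classes}")
    n = len(eig)
    floor = math.ceil(min_per_leaf_fraction * n)
    X = eig[features].to_numpy(dtype=float)
    yi = np.array([classes.index(v) for v in y])

    def leaf(idx) -> Leaf:
        counts = np.bincount(yi[idx], minlength=2)
        label = classes[int(np.argmax(counts))]  # argmax ties -> smaller code
        return Leaf(label, {classes[i]: int(counts[i]) for i in range(2)})

    def best_split(idx):
        h0 = _entropy(np.bincount(yi[idx], minlength=2))
        best = None  # (ratio, f_idx, threshold, left_mask)
        for fi in range(len(features)):
            x = X[idx, fi]
            order = np.argsort(x, kind="stable")
            xs, ys = x[order], yi[idx][order]
            distinct = np.nonzero(np.diff(xs) > 0)[0]
            for j in distinct:
                thr = (xs[j] + xs[j + 1]) / 2.0
                nl = j + 1
                nr = len(xs) - nl
                if nl < floor or nr < floor:
                    continue
                cl = np.bincount(ys[:nl], minlength=2)
                cr = np.bincount(ys[nl:], minlength=2)
                gain = h0 - (nl * _entropy(cl) + nr * _entropy(cr)) / len(xs)
                if gain <= 1e-12:
                    continue
                split_info = _entropy(np.array([nl, nr]))
                ratio = gain / split_info if split_info > 0 else 0.0
                if best is None or ratio > best[0] + 1e-12:
                    best = (ratio, fi, thr)
        return best

    def grow(idx):
        if len(np.unique(yi[idx])) == 1:
            return leaf(idx)
        best = best_split(idx)
        if best is None:
            return leaf(idx)
        _, fi, thr = best
        mask = X[idx, fi] <= thr
        return Split(features[fi], float(thr), grow(idx[mask]), grow(idx[~mask]))

    if n < 2 * floor:
        warnings.warn("too few samples for any split; returning a single leaf")
        root = leaf(np.arange(n))
    else:
        root = grow(np.arange(n))
    return DecisionTree(root, classes, min_per_leaf_fraction)


def predict(tree: DecisionTree, eig: pd.DataFrame) -> pd.Series:
    """Route samples through the tree; ``value <= threshold`` goes left."""
    missing = [f for f in tree.features() if f not in eig.columns]
    if missing:
        raise ValueError(f"eigengene matrix lacks tree feature(s): {missing}")
    out = []
    for _, row in eig.iterrows():
        node = tree.root
        while isinstance(node, Split):
            node = node.left if row[node.feature] <= node.threshold else node.right
        out.append(node.label)
    return pd.Series(out, index=eig.index)


def confusion(pred: pd.Series, truth: pd.Series) -> tuple[pd.DataFrame, dict]:
    """2x2 confusion counts (rows = truth) and per-class sensitivity."""
    if set(pred.index) != set(truth.index):
        raise ValueError("prediction and truth cover different samples")
    truth = truth.loc[pred.index]
    classes = sorted(truth.unique())
    extra = set(pred.unique()) - set(classes)
    if extra:
        raise ValueError(f"predicted labels not in truth: {sorted(extra, key=str)}")
    table = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(truth, pred):
        table.loc[t, p] += 1
    sens = {
        c: (table.loc[c, c] / table.loc[c].sum()) if table.loc[c].sum() else float("nan")
        for c in classes
    }
    return table, sens


@dataclass
class CompactionResult:
    """Trajectory of greedy lowest-|weight| gene removal."""

    removal_order: list  # (gene id, |weight| at removal)
    trajectory: list  # (remaining gene count, {class: train accuracy})
    selected_genes: list
    model: EigengeneModel  # reduced model over the tree's feature modules


def _class_accuracy(tree, eig, labels) -> dict:
    _, sens = confusion(predict(tree, eig), labels)
    return sens


def compact_tree(
    tree: DecisionTree,
    model: EigengeneModel,
    ds: ExpressionDataset,
    labels: pd.Series,
    min_genes: int = 1,
    max_drop: float = 0.05,
) -> CompactionResult:
    """Greedily shrink the gene set backing the tree's feature modules.

    Each iteration removes the gene with the smallest absolute weight across
    all feature modules (ties: lexicographic gene id; modules reduced to one
    gene are irreducible), renormalizes the remaining weight sub-vectors,
    re-projects eigengenes and re-evaluates per-class training accuracy with
    the tree structure and thresholds unchanged. Stops when a removal would
    push any class accuracy more than ``max_drop`` below its initial value,
    or when ``min_genes`` genes remain.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    feats = tree.features()
    missing = [f for f in feats if f not in model.modules]
    if missing:
        raise ValueError(f"model lacks tree feature module(s): {missing}")
    work = EigengeneModel(
        {m: copy.deepcopy(model.modules[m]) for m in feats}, dict(model.metadata)
    )
    for me in work.modules.values():
        me.weights = me.weights / np.linalg.norm(me.weights)

    def n_genes() -> int:
        return sum(len(me.genes) for me in work.modules.values())

    eig = project_eigengenes(work, ds)
    acc0 = _class_accuracy(tree, eig, labels)
    trajectory = [(n_genes(), dict(acc0))]
    removal_order: list = []

    while n_genes() > min_genes:
        pool = [
            (abs(float(me.weights[i])), g, m)
            for m, me in work.modules.items()
            if len(me.genes) > 1
            for i, g in enumerate(me.genes)
        ]
        if not pool:
            break
        w_abs, gene, m = min(pool, key=lambda t: (t[0], t[1]))
        me = work.modules[m]
        i = me.genes.index(gene)
        saved_genes, saved_w = list(me.genes), me.weights.copy()
        me.genes = me.genes[:i] + me.genes[i + 1 :]
        w = np.delete(me.weights, i)
        me.weights = w / np.linalg.norm(w)
        eig = project_eigengenes(work, ds)
        acc = _class_accuracy(tree, eig, labels)
        if any(acc[c] < acc0[c] - max_drop for c in acc0):
            me.genes, me.weights = saved_genes, saved_w
            break
        removal_order.append((gene, w_abs))
        trajectory.append((n_genes(), dict(acc)))

    return CompactionResult(removal_order, trajectory, work.genes(), work)
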