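"""Discrete Bayesian-network structure learning over eigengenes + Disease.

Eigengenes are discretized into quantile levels and joined with a binary
Disease variable. Structure is learned by greedy hill climbing over DAGs
(add/delete/reverse one arc) maximizing the decomposable multinomial BIC
score; arcs into the Disease node are blacklisted so modules can only be its
children. A consensus network averages structures over bootstrap resamples,
keeping arcs whose direction-specific frequency reaches a strength cut.
The children of Disease are the modules most dependent on the disease label
and serve as classifier features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd

DISEASE = "Disease"


@dataclass
class DiscreteEigengeneTable:
    """Samples x variables table of level indices plus per-variable cardinality."""

    data: pd.DataFrame  # integer level indices
    cardinality: dict  # variable -> number of levels

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)


@dataclass
class BayesNet:
    """A DAG over module ids + Disease with per-arc consensus strengths."""

    nodes: list
    arcs: set  # of (parent, child) tuples
    strength: dict = field(default_factory=dict)  # arc -> [0, 1]
    score: float = float("nan")

    def children(self, node) -> list:
        return sorted((v for u, v in self.arcs if u == node), key=str)

    def parents(self, node) -> list:
        return sorted((u for u, v in self.arcs if v == node), key=str)

    def to_dot(self) -> str:
        lines = ["digraph eigengene_network {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs, key=lambda a: (str(a[0]), str(a[1]))):
            s = self.strength.get((u, v), 1.0)
            lines.append(f'  "{u}" -> "{v}" [label="{s:.2f}"];')
        lines.append("}")
        return "\n".join(lines)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"from": u, "to": v, "strength": self.strength.get((u, v), 1.0)}
            for u, v in sorted(self.arcs, key=lambda a: (str(a[0]), str(a[1])))
        ]
        return pd.DataFrame(rows, columns=["from", "to", "strength"])


def discretize_eigengenes(
    eig: pd.DataFrame, labels: pd.Series, n_levels: int = 3, positive_label=None
) -> DiscreteEigengeneTable:
    """Quantile-discretize eigengene columns and append a binary Disease node.

    Level boundaries are the empirical quantiles at ``k / n_levels``. Columns
    with too few distinct values collapse to fewer levels (warning). The
    Disease column is 1 for ``positive_label`` (default: the
    lexicographically larger of the two labels) and 0 otherwise.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    unknown = eig.index.difference(labels.index)
    if len(unknown) > 0:
        raise ValueError(f"samples without label: {list(unknown)[:5]}")
    classes = sorted(labels.loc[eig.index].unique())
    if len(classes) != 2:
        raise ValueError(f"exactly 2 condition labels required, got {classes}")
    if positive_label is None:
        positive_label = classes[1]
    data = {}
    cardinality = {}
    for col in eig.columns:
        x = eig[col].to_numpy(dtype=float)
        cuts = np.unique(np.quantile(x, [k / n_levels for k in range(1, n_levels)]))
        levels = np.searchsorted(cuts, x, side="left")
        n_obs = len(np.unique(levels))
        if n_obs < n_levels:
            warnings.warn(
                f"column {col}: only {n_obs} level(s) after discretization"
            )
        # re-index levels densely so cardinality matches observed levels
        _, dense = np.unique(levels, return_inverse=True)
        data[col] = dense
        cardinality[col] = int(dense.max()) + 1
    data[DISEASE] = (labels.loc[eig.index].to_numpy() == positive_label).astype(int)
    cardinality[DISEASE] = 2
    return DiscreteEigengeneTable(pd.DataFrame(data, index=eig.index), cardinality)


# -- BIC scoring -------------------------------------------------------------


def _local_bic(X: np.ndarray, cards: list[int], node: int, parents: tuple) -> float:
    """BIC contribution of one node given its parent set (multinomial CPDs)."""
    n = X.shape[0]
    r = cards[node]
    x = X[:, node]
    if parents:
        q = 1
        idx = np.zeros(n, dtype=np.int64)
        for p in parents:
            idx = idx * cards[p] + X[:, p]
            q *= cards[p]
    else:
        q = 1
        idx = np.zeros(n, dtype=np.int64)
    joint = np.bincount(idx * r + x, minlength=q * r).reshape(q, r).astype(float)
    nij = joint.sum(axis=1, keepdims=True)
    nz = joint > 0
    ll = float((joint[nz] * np.log(joint[nz] / np.broadcast_to(nij, joint.shape)[nz])).sum())
    return ll - 0.5 * np.log(n) * (r - 1) * q


def score_dag(table: DiscreteEigengeneTable, arcs) -> float:
    """Total BIC score of a fixed DAG on the table."""
    variables = table.variables
    X = table.data.to_numpy(dtype=np.int64)
    cards = [table.cardinality[v] for v in variables]
    pos = {v: i for i, v in enumerate(variables)}
    total = 0.0
    for v in variables:
        parents = tuple(sorted((pos[u] for u, w in arcs if w == v)))
        total += _local_bic(X, cards, pos[v], parents)
    return total


def _reachable(children: dict, src, dst) -> bool:
    stack = [src]
    seen = set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(children.get(u, ()))
    return False


def _random_dag(variables, blacklist, rng, p_arc: float = 0.3) -> set:
    """Random acyclic arc set respecting the blacklist (restart seeds)."""
    arcs: set = set()
    children: dict = {v: set() for v in variables}
    pairs = [(u, v) for u, v in permutations(variables, 2) if v not in blacklist]
    for i in rng.permutation(len(pairs)):
        u, v = pairs[i]
        if rng.random() < p_arc and not _reachable(children, v, u):
            arcs.add((u, v))
            children[u].add(v)
    return arcs


def learn_structure(
    table: DiscreteEigengeneTable,
    blacklist_into=frozenset({DISEASE}),
    seed: int = 0,
    restarts: int = 0,
) -> BayesNet:
    """Greedy hill climbing over DAGs maximizing the multinomial BIC score.

    Single-arc add/delete/reverse moves; arcs into blacklisted nodes are
    never proposed; the seed shuffles the evaluation order of candidate
    moves so score ties break deterministically but without a fixed
    node-order bias.

    ``restarts`` additional greedy runs start from random DAGs (seeds
    ``seed + 1 .. seed + restarts``) and the best-scoring local optimum is
    returned. Restarts matter for dependence structures invisible to
    single-arc moves from the empty graph, such as parity (XOR) colliders
    whose parents are marginally independent of the child.
    """
    if table.n_samples < 10:
        raise ValueError("structure learning needs at least 10 samples")
    variables = table.variables
    X = table.data.to_numpy(dtype=np.int64)
    cards = [table.cardinality[v] for v in variables]
    pos = {v: i for i, v in enumerate(variables)}
    blacklist = set(blacklist_into)
    cache: dict = {}

    def local(v, pset) -> float:
        key = (v, frozenset(pset))
        if key not in cache:
            cache[key] = _local_bic(X, cards, pos[v], tuple(sorted(pos[u] for u in pset)))
        return cache[key]

    best_arcs: set = set()
    best_total = -math.inf
    for attempt in range(restarts + 1):
        rng = np.random.default_rng(seed + attempt)
        init = set() if attempt == 0 else _random_dag(variables, blacklist, rng)
        arcs, total = _greedy_climb(variables, blacklist, init, local, rng)
        if total > best_total + 1e-12:
            best_total = total
            best_arcs = arcs
    return BayesNet(
        list(variables), best_arcs, {a: 1.0 for a in best_arcs}, float(best_total)
    )


def _greedy_climb(variables, blacklist, init_arcs, local, rng):
    parents: dict = {v: set() for v in variables}
    children: dict = {v: set() for v in variables}
    for u, v in init_arcs:
        parents[v].add(u)
        children[u].add(v)
    score = {v: local(v, parents[v]) for v in variables}

    while True:
        moves = []
        for u, v in permutations(variables, 2):
            has = u in parents[v]
            if not has and v not in blacklist and not _reachable(children, v, u):
                delta = local(v, parents[v] | {u}) - score[v]
                moves.append(("add", u, v, delta))
            if has:
                delta = local(v, parents[v] - {u}) - score[v]
                moves.append(("del", u, v, delta))
                if u not in blacklist:
                    children[u].discard(v)
                    cyclic = _reachable(children, u, v)
                    children[u].add(v)
                    if not cyclic:
                        delta = (
                            local(v, parents[v] - {u})
                            - score[v]
                            + local(u, parents[u] | {v})
                            - score[u]
                        )
                        moves.append(("rev", u, v, delta))
        if not moves:
            break
        order = rng.permutation(len(moves))
        best = None
        for i in order:
            if best is None or moves[i][3] > moves[best][3] + 1e-12:
                best = i
        op, u, v, delta = moves[best]
        if delta <= 1e-10:
            break
        if op == "add":
            parents[v].add(u)
            children[u].add(v)
        elif op == "del":
            parents[v].discard(u)
            children[u].discard(v)
        else:
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            score[u] = local(u, parents[u])
        score[v] = local(v, parents[v])

    arcs = {(u, v) for v in variables for u in parents[v]}
    return arcs, float(sum(score.values()))


def consensus_structure(
    table: DiscreteEigengeneTable,
    blacklist_into=frozenset({DISEASE}),
    n_boot: int = 100,
    strength_cut: float = 0.5,
    seed: int = 0,
    restarts: int = 0,
) -> BayesNet:
    """Bootstrap-averaged structure: keep arcs learned in >= strength_cut of
    resamples (direction-specific), breaking any residual cycle by dropping
    its weakest arc. ``restarts`` is forwarded to every per-resample search."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < strength_cut <= 1:
        raise ValueError("strength_cut must be in (0, 1]")
    n = table.n_samples
    counts: dict = {}
    for b in range(1, n_boot + 1):
        rng = np.random.default_rng(seed + b)
        rows = rng.integers(0, n, size=n)
        boot = DiscreteEigengeneTable(table.data.iloc[rows], table.cardinality)
        net = learn_structure(boot, blacklist_into, seed=seed + b, restarts=restarts)
        for a in net.arcs:
            counts[a] = counts.get(a, 0) + 1
    strength = {a: c / n_boot for a, c in counts.items()}
    kept = {a for a, s in strength.items() if s >= strength_cut}
    g = nx.DiGraph(kept)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (strength[(e[0], e[1])], str(e)))
        g.remove_edge(weakest[0], weakest[1])
        kept.discard((weakest[0], weakest[1]))
    return BayesNet(
        list(table.variables),
        kept,
        {a: strength[a] for a in kept},
        score_dag(table, kept),
    )


def disease_children(net: BayesNet, node=DISEASE) -> list:
    """Modules with an arc from Disease, by descending strength then id."""
    if node not in net.nodes:
        raise ValueError(f"{node!r} not in network")
    kids = [(v, net.strength.get((node, v), 1.0)) for u, v in net.arcs if u == node]
    kids.sort(key=lambda kv: (-kv[1], str(kv[0])))
    return [v for v, _ in kids]
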