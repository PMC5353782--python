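"""Statistical primitives: Welch's t-test, hypergeometric overrepresentation,
Bonferroni correction, and module/gene-set enrichment."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sample Welch t-test (unequal variances).

    Returns ``(t, df, p)`` where ``t = (mean(x) - mean(y)) / sqrt(sx2/nx +
    sy2/ny)``, ``df`` is the Welch-Satterthwaite approximation and ``p`` is
    the two-sided tail probability of the t distribution.

    Degenerate inputs: if both sample variances are zero the statistic is
    undefined; equal means give ``(0, nx+ny-2, 1)`` and differing means give
    ``p = 0`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        warnings.warn(
            "zero variance in both groups with differing means; p-value set to 0",
            stacklevel=2,
        )
        return math.copysign(math.inf, mx - my), float(nx + ny - 2), 0.0
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def hypergeometric_overrep(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric (overrepresentation) p-value.

    Probability of drawing at least ``k`` marked items when ``n`` items are
    drawn without replacement from a universe of ``N`` items of which ``K``
    are marked: ``P(X >= k)``.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if n > N or K > N or k > min(n, K):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # survival function is evaluated in log space internally by scipy and is
    # accurate for extreme tails (p ~ 1e-300)
    p = float(_sps.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bonferroni(p) -> np.ndarray:
    """Bonferroni family-wise correction: ``p_adj = min(1, m * p)``."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class EnrichmentResult:
    """One module x gene-set overrepresentation test."""

    module: int
    gene_set: str
    N: int  # universe size
    K: int  # gene-set size (after intersecting with the universe)
    n: int  # module size (within the universe)
    k: int  # overlap
    p: float
    p_adj: float


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, member genes)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def module_enrichment(modules, gene_sets: dict[str, set[str]], universe) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of every (module, gene set) pair.

    ``universe`` must contain all module genes; each gene set is intersected
    with the universe before testing. p-values are Bonferroni-corrected over
    all pairs tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module_genes = {
        m: set(modules.genes_in(m)) for m in sorted(modules.module_sizes) if m != 0
    }
    for m, genes in module_genes.items():
        if not genes <= universe:
            raise ValueError(f"module {m} contains genes outside the universe")
    N = len(universe)
    results: list[EnrichmentResult] = []
    for m, mg in module_genes.items():
        for name in sorted(gene_sets):
            sg = gene_sets[name] & universe
            k = len(mg & sg)
            p = hypergeometric_overrep(k, len(mg), len(sg), N)
            results.append(EnrichmentResult(m, name, N, len(sg), len(mg), k, p, p))
    adj = bonferroni([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results
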