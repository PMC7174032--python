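"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: shortest paths are
found by exhaustive simple-path enumeration, efficiencies by summing over
that enumeration, FDR by a literal step-up, OLS by normal equations.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_degree(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                k[i] += 1
    return k


def brute_force_shortest_paths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path on lengths 1/w by enumerating simple paths."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = list(range(n))
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            best = np.inf
            middles = [v for v in nodes if v not in (src, dst)]
            for r in range(len(middles) + 1):
                for mid in itertools.permutations(middles, r):
                    path = (src, *mid, dst)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a, b]
                    if ok:
                        best = min(best, length)
            d[src, dst] = best
    return d


def brute_force_global_efficiency(w: np.ndarray) -> float:
    d = brute_force_shortest_paths(w)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_force_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = brute_force_global_efficiency(sub)
    return out


def brute_force_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering with max-normalization, triple loops."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wh = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def stepup_fdr(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals from the normal equations (X'X)^-1 X'y."""
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return y - design @ beta


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.5) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < density
    vals = rng.uniform(0.1, 2.0, iu[0].size) * present
    w[iu] = vals
    w += w.T
    return w


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence of two loading vectors (sign-invariant)."""
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return abs(float(a @ b)) / denom if denom > 0 else 0.0


def matched_congruence(est: np.ndarray, planted: np.ndarray) -> float:
    """Min per-factor congruence after best column matching of est to planted."""
    k = planted.shape[1]
    best = -np.inf
    for perm in itertools.permutations(range(est.shape[1]), k):
        score = min(congruence(est[:, perm[j]], planted[:, j]) for j in range(k))
        best = max(best, score)
    return best
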