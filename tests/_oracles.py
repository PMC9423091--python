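"""Independent brute-force oracles used only by the test suite.

Each function recomputes a quantity from first principles (double loops,
recursions, Monte-Carlo gene dropping) without touching the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def g_additive_bruteforce(dosage: np.ndarray) -> np.ndarray:
    """VanRaden G by an explicit double loop over individuals."""
    n, m = dosage.shape
    p = dosage.mean(axis=0) / 2.0
    w = dosage - 2.0 * p
    denom = 2.0 * sum(p[k] * (1 - p[k]) for k in range(m))
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = sum(w[i, k] * w[j, k] for k in range(m)) / denom
    return G


def g_dominance_bruteforce(dosage: np.ndarray) -> np.ndarray:
    """Vitezica dominance matrix by explicit loops (integer dosages)."""
    n, m = dosage.shape
    p = dosage.mean(axis=0) / 2.0
    q = 1.0 - p
    H = np.zeros((n, m))
    for i in range(n):
        for k in range(m):
            x = dosage[i, k]
            if x == 0:
                H[i, k] = -2.0 * q[k] ** 2
            elif x == 1:
                H[i, k] = 2.0 * p[k] * q[k]
            else:
                H[i, k] = -2.0 * p[k] ** 2
    denom = sum((2.0 * p[k] * q[k]) ** 2 for k in range(m))
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = sum(H[i, k] * H[j, k] for k in range(m)) / denom
    return G


def kinship_recursive(ped: pd.DataFrame):
    """Memoized coancestry (kinship) recursion; returns f(i, j)."""
    parents = {r["id"]: (r["mother"] if pd.notna(r["mother"]) else None,
                         r["father"] if pd.notna(r["father"]) else None)
               for _, r in ped.iterrows()}
    order = {i: k for k, i in enumerate(ped["id"])}
    cache: dict = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        key = (a, b) if order[a] <= order[b] else (b, a)
        if key in cache:
            return cache[key]
        # recurse on the later-added individual so the recursion terminates
        if order[a] < order[b]:
            a, b = b, a
        ma, fa = parents[a]
        if a == b:
            val = 0.5 * (1.0 + f(ma, fa))
        else:
            val = 0.5 * (f(ma, b) + f(fa, b))
        cache[key] = val
        return val

    return f


def a_matrix_recursive(ped: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix as twice the recursive kinship."""
    f = kinship_recursive(ped)
    ids = list(ped["id"])
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 2.0 * f(ids[i], ids[j])
    return A


def d_matrix_recursive(ped: pd.DataFrame) -> np.ndarray:
    """Pedigree dominance relationships from parental kinships
    (non-inbred diagonal convention)."""
    f = kinship_recursive(ped)
    parents = {r["id"]: (r["mother"] if pd.notna(r["mother"]) else None,
                         r["father"] if pd.notna(r["father"]) else None)
               for _, r in ped.iterrows()}
    ids = list(ped["id"])
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                D[i, j] = 1.0
                continue
            mi, fi = parents[ids[i]]
            mj, fj = parents[ids[j]]
            if None in (mi, fi, mj, fj):
                continue
            D[i, j] = (2.0 * f(fi, fj)) * (2.0 * f(mi, mj)) / 4.0 \
                + (2.0 * f(fi, mj)) * (2.0 * f(mi, fj)) / 4.0
    return D


def gene_drop_relationship(ped: pd.DataFrame, n_drops: int, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo additive relationship by dropping alleles through the
    pedigree.  Returns (estimate, MC standard error) matrices.

    Each founder receives two unique alleles; each offspring inherits one
    random allele from each parent (unknown parents contribute fresh
    unique alleles).  The additive relationship is twice the probability
    that a random allele from i is identical by descent to a random
    allele from j.
    """
    rng = np.random.default_rng(seed)
    ids = list(ped["id"])
    idx = {v: k for k, v in enumerate(ids)}
    parents = [(r["mother"] if pd.notna(r["mother"]) else None,
                r["father"] if pd.notna(r["father"]) else None)
               for _, r in ped.iterrows()]
    n = len(ids)
    alleles = np.zeros((n_drops, n, 2), dtype=np.int64)
    counter = 0
    for k, (m, f) in enumerate(parents):
        for slot, par in enumerate((m, f)):
            if par is None:
                alleles[:, k, slot] = counter
                counter += 1
            else:
                pk = idx[par]
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, k, slot] = alleles[np.arange(n_drops), pk, pick]
    est = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ibd = sum(
                (alleles[:, i, a] == alleles[:, j, b]).astype(float)
                for a in (0, 1) for b in (0, 1)
            ) / 4.0
            if i == j:
                ibd = 0.5 + 0.5 * (alleles[:, i, 0] == alleles[:, i, 1])
            vals = 2.0 * ibd
            est[i, j] = vals.mean()
            se[i, j] = vals.std(ddof=1) / np.sqrt(n_drops)
    return est, se


def status_number_bruteforce(A: np.ndarray) -> float:
    """Status number by an explicit double loop over ordered pairs."""
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += A[i, j] / 2.0
    theta = total / (n * n)
    return 1.0 / (2.0 * theta)


def balanced_oneway_reml(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Closed-form REML (= ANOVA) estimators for a balanced one-way
    random-effects model: returns (between, within) variances."""
    levels = np.unique(groups)
    s = len(levels)
    m = len(y) // s
    means = np.array([y[groups == g].mean() for g in levels])
    msb = m * ((means - y.mean()) ** 2).sum() / (s - 1)
    msw = sum(((y[groups == g] - means[k]) ** 2).sum()
              for k, g in enumerate(levels)) / (s * (m - 1))
    return (msb - msw) / m, msw
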