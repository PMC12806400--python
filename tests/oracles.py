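"""Independent oracles used across the test suite.

Each oracle deliberately takes a different computational route than the
package implementation it checks: exhaustive enumeration instead of Monte
Carlo, sklearn isotonic regression instead of scipy, direct set arithmetic
instead of the parser, rank-then-Pearson instead of scipy.stats.spearmanr.
"""

from __future__ import annotations

import itertools

import numpy as np


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho via explicit average ranks followed by Pearson."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def exact_community_probs(freq: np.ndarray, n: int) -> dict[frozenset, float]:
    """P(unordered community of size n) under sequential frequency-weighted
    draws without replacement, by exhaustive enumeration of ordered draws."""
    w = np.asarray(freq, dtype=float)
    w = w / w.sum()
    probs: dict[frozenset, float] = {}
    for combo in itertools.combinations(range(len(w)), n):
        p = 0.0
        for perm in itertools.permutations(combo):
            q, rem = 1.0, 1.0
            for sp in perm:
                q *= w[sp] / rem
                rem -= w[sp]
            p += q
        probs[frozenset(combo)] = p
    return probs


def exact_raup_crick(freq: np.ndarray, n1: int, n2: int, obs: int) -> float:
    """Exact RC value (half-weight tie convention) for a pool with the given
    occurrence frequencies and a pair with richness n1, n2 sharing obs."""
    p1 = exact_community_probs(freq, n1)
    p2 = exact_community_probs(freq, n2)
    gt = eq = 0.0
    for a, pa in p1.items():
        for b, pb in p2.items():
            shared = len(a & b)
            if shared > obs:
                gt += pa * pb
            elif shared == obs:
                eq += pa * pb
    return 2.0 * ((gt + 0.5 * eq) - 0.5)


def kruskal_stress_sklearn(delta: np.ndarray, dist: np.ndarray) -> float:
    """Kruskal stress-1 with disparities from sklearn's isotonic regression."""
    from sklearn.isotonic import IsotonicRegression

    dhat = IsotonicRegression(increasing=True).fit_transform(delta, dist)
    return float(np.sqrt(((dhat - dist) ** 2).sum() / (dist**2).sum()))


def mantel_exact_oracle(d1: np.ndarray, d2: np.ndarray, method: str = "spearman"):
    """Exhaustive-permutation Mantel (r, p) for small matrices."""
    from scipy.stats import rankdata

    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(a, b):
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    v1 = d1[iu]
    r_obs = corr(v1, d2[iu])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        count += corr(v1, d2[np.ix_(p, p)][iu]) >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


def anosim_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R from independently computed mean ranks."""
    from scipy.stats import rankdata

    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    between = [r for r, i, j in zip(ranks, iu[0], iu[1]) if labels[i] != labels[j]]
    within = [r for r, i, j in zip(ranks, iu[0], iu[1]) if labels[i] == labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4.0)
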