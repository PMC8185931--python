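"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route separate from the package's
implementation: dynamic-programming edit distance, a vectorized all-pairs
DP table, a restarted-Polyak projected-subgradient solver for the
box-constrained nuclear-norm problem, and a pairwise-concordance
(Mann-Whitney) AUC.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Classic full-table dynamic-programming edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def recursive_levenshtein(a: str, b: str) -> int:
    """Exhaustive memoized recursion over the three edit operations."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def all_pairs_levenshtein(strings: list[str], max_len: int) -> np.ndarray:
    """Edit-distance matrix over all string pairs, by vectorized DP.

    Strings are padded to ``max_len``; the recurrence runs over the padded
    (max_len+1)^2 prefix grid with (N, N)-shaped cost arrays and the final
    distances are gathered at each pair's true length coordinates.
    """
    n = len(strings)
    lens = np.array([len(s) for s in strings])
    enc = np.zeros((n, max_len), dtype=np.int8)
    for idx, s in enumerate(strings):
        enc[idx, : len(s)] = [ord(c) for c in s]
    table = np.empty((max_len + 1, max_len + 1, n, n), dtype=np.int16)
    for i in range(max_len + 1):
        table[i, 0] = i
    for j in range(max_len + 1):
        table[0, j] = j
    for i in range(1, max_len + 1):
        ai = enc[:, i - 1][:, None]  # (n, 1)
        for j in range(1, max_len + 1):
            bj = enc[:, j - 1][None, :]  # (1, n)
            sub = table[i - 1, j - 1] + (ai != bj)
            table[i, j] = np.minimum(np.minimum(table[i - 1, j] + 1,
                                                table[i, j - 1] + 1), sub)
    return table[lens[:, None], lens[None, :], np.arange(n)[:, None], np.arange(n)[None, :]]


def nuclear_objective(Z: np.ndarray, M: np.ndarray, alpha: float) -> float:
    """Objective of the box-constrained denoising problem at Z."""
    return float(
        np.linalg.norm(Z, "nuc") + 0.5 * alpha * np.linalg.norm(Z - M) ** 2
    )


def projected_subgradient(
    M: np.ndarray, alpha: float = 1.0, iters: int = 30000
) -> np.ndarray:
    """Solve min ||Z||_* + (alpha/2)||Z - M||_F^2 s.t. 0 <= Z <= 1.

    Projected subgradient with a restarted Polyak step: the unknown optimal
    value is estimated as (best seen) - delta, with delta halved whenever
    progress stalls.  Returns the best iterate.
    """
    Z = np.clip(M, 0.0, 1.0)
    best = Z.copy()
    f_best = nuclear_objective(Z, M, alpha)
    delta = 0.1 * max(f_best, 1.0)
    stall = 0
    for _ in range(iters):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        g = (U * (s > 1e-12)) @ Vt + alpha * (Z - M)
        f = nuclear_objective(Z, M, alpha)
        if f < f_best - 1e-14:
            f_best, best, stall = f, Z.copy(), 0
        else:
            stall += 1
            if stall > 500:
                delta *= 0.5
                stall = 0
        step = (f - (f_best - delta)) / max(float(np.sum(g * g)), 1e-15)
        Z = np.clip(Z - step * g, 0.0, 1.0)
    return best


def concordance_auc(scores, labels) -> float:
    """Mann-Whitney AUC: concordant positive/negative pairs, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))
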