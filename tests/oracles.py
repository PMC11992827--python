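"""Independent reference implementations used only to cross-check the
package: single-pair Dijkstra, brute-force pair-counting AUC, and a direct
NIPALS partial-least-squares fit for VIP scores."""

from __future__ import annotations

import heapq

import numpy as np


def dijkstra(A: np.ndarray, source: int) -> np.ndarray:
    """Single-source shortest distances on a dense non-negative matrix."""
    n = A.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v in range(n):
            w = A[u, v]
            if np.isfinite(w) and d + w < dist[v]:
                dist[v] = d + w
                heapq.heappush(heap, (d + w, v))
    return dist


def pair_counting_auc(scores, labels) -> float:
    """Fraction of positive-negative pairs ordered correctly; ties count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def nipals_vip(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """VIP scores from a from-scratch NIPALS PLS1 fit (X: samples x features,
    y: centred class indicator)."""
    X = X - X.mean(axis=0)
    y = y - y.mean()
    n, p = X.shape
    W, T, Q = [], [], []
    Xr, yr = X.copy(), y.copy().astype(float)
    for _ in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = Xr @ w
        tt = t @ t
        if tt == 0:
            break
        q = (yr @ t) / tt
        p_load = (Xr.T @ t) / tt
        Xr = Xr - np.outer(t, p_load)
        yr = yr - q * t
        W.append(w)
        T.append(t)
        Q.append(q)
    W = np.array(W).T  # p x A
    T = np.array(T).T  # n x A
    Q = np.array(Q)
    ss = (T ** 2).sum(axis=0) * Q ** 2
    vip2 = p * (W ** 2) @ ss / ss.sum()
    return np.sqrt(vip2)
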