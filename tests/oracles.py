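"""Independent reference implementations used only as test oracles.

Each function is a literal, unoptimized transcription of the defining
formulas (dicts and explicit loops; for Bradley-Terry, a generic
numerical likelihood maximization).  They deliberately share no code with
the package under test.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import minimize


def elo_oracle(trials, k=100.0, start=0.0, base=10.0, divisor=400.0):
    """Step-by-step Elo over (winner, loser, draw) tuples -> score dict."""
    scores: dict[str, float] = {}
    for w, l, d in trials:
        scores.setdefault(w, start)
        scores.setdefault(l, start)
    for w, l, d in trials:
        s1, s2 = scores[w], scores[l]
        e1 = 1.0 / (1.0 + base ** ((s2 - s1) / divisor))
        e2 = 1.0 / (1.0 + base ** ((s1 - s2) / divisor))
        o1, o2 = (0.5, 0.5) if d else (1.0, 0.0)
        scores[w] = s1 + k * (o1 - e1)
        scores[l] = s2 + k * (o2 - e2)
    return scores


def consistency_oracle(trials, k=100.0, start=0.0, base=10.0, divisor=400.0):
    """Literal u/w bookkeeping -> (R, R_weighted, N) or (None, None, 0)."""
    scores: dict[str, float] = {}
    for w, l, d in trials:
        scores.setdefault(w, start)
        scores.setdefault(l, start)
    u, wt = [], []
    for w, l, d in trials:
        s1, s2 = scores[w], scores[l]
        if not d and s1 != s2:
            u.append(1 if s1 < s2 else 0)
            wt.append(abs(s1 - s2))
        e1 = 1.0 / (1.0 + base ** ((s2 - s1) / divisor))
        o1 = 0.5 if d else 1.0
        delta = k * (o1 - e1)
        scores[w] = s1 + delta
        scores[l] = s2 - delta
    N = len(u)
    if N == 0:
        return None, None, 0
    R = 1.0 - sum(u) / N
    Rw = 1.0 - sum(ui * wi for ui, wi in zip(u, wt)) / sum(wt)
    return R, Rw, N


def melo_oracle(trials, k=100.0, start=0.0):
    """All-permutation average of final Elo scores (tiny trial lists)."""
    acc: dict[str, float] = {}
    n = 0
    for perm in permutations(trials):
        final = elo_oracle(list(perm), k=k, start=start)
        for s, v in final.items():
            acc[s] = acc.get(s, 0.0) + v
        n += 1
    return {s: v / n for s, v in acc.items()}


def bt_oracle(wins: np.ndarray) -> np.ndarray:
    """Maximize the Bradley-Terry log-likelihood numerically.

    Softmax parameterization over n-1 free log-worths; generic quasi-Newton
    optimizer, nothing shared with the MM fixed point.
    """
    wins = np.asarray(wins, dtype=float)
    n = wins.shape[0]

    def neg_ll(free):
        logw = np.concatenate([[0.0], free])
        w = np.exp(logw - logw.max())
        w = w / w.sum()
        ll = 0.0
        for i in range(n):
            for j in range(n):
                if i != j and wins[i, j] > 0:
                    ll += wins[i, j] * np.log(w[i] / (w[i] + w[j]))
        return -ll

    best = None
    for x0 in (np.zeros(n - 1), np.full(n - 1, 0.5)):
        res = minimize(neg_ll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    logw = np.concatenate([[0.0], best.x])
    w = np.exp(logw - logw.max())
    return w / w.sum()
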