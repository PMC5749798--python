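"""Bradley-Terry worth parameters as an order-free cross-check for mElo.

Under the Bradley-Terry model stimulus i is chosen over stimulus j with
probability pi_i / (pi_i + pi_j).  The positive "worths" pi are fit by
maximum likelihood with the classical Zermelo/MM fixed point,

    pi_i  <-  W_i / sum_{j != i} n_ij / (pi_i + pi_j),

where W_i is i's total number of wins and n_ij the number of comparisons
between i and j; each iteration provably does not decrease the likelihood.
Worths are normalized to the unit simplex and are typically log-transformed
before correlating with other measures (worth distributions are strongly
skewed).  Because the likelihood depends only on win counts, the fit is
invariant to trial order — which is exactly what makes it a useful
reference for the sequence-averaged Elo scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .core import TrialSequence

__all__ = [
    "WorthVector",
    "DisconnectedComparisonsError",
    "DegenerateRecordError",
    "count_wins",
    "fit_bt",
    "bt_scores_from_trials",
]


class DisconnectedComparisonsError(ValueError):
    """The comparison graph splits into components with no trials between
    them; relative worths across components are not estimable."""

    def __init__(self, components: list[list[str]]):
        self.components = components
        super().__init__(
            "comparison graph is disconnected; components: "
            + "; ".join("{" + ", ".join(map(str, c)) + "}" for c in components)
        )


class DegenerateRecordError(ValueError):
    """Some stimulus won every trial or lost every trial; its MLE worth
    diverges.  A small pseudocount (e.g. 0.5) regularizes this."""


@dataclass(frozen=True)
class WorthVector:
    """Fitted worths on the unit simplex, with their natural logs."""

    worth: pd.Series
    log_worth: pd.Series
    n_iter: int
    converged: bool
    log_likelihood: float


def count_wins(seq: TrialSequence) -> pd.DataFrame:
    """Win matrix from a trial sequence: entry (i, j) counts wins of i
    over j.  A draw contributes half a win to each side."""
    labels = list(seq.roster)
    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    w_idx, l_idx, draws = seq.encoded()
    for w, l, d in zip(w_idx, l_idx, draws):
        if d:
            mat[w, l] += 0.5
            mat[l, w] += 0.5
        else:
            mat[w, l] += 1.0
    return pd.DataFrame(mat, index=labels, columns=labels)


def bt_log_likelihood(wins: np.ndarray, worth: np.ndarray) -> float:
    """Log-likelihood of a worth vector for a win-count matrix."""
    n_ij = wins + wins.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = wins * (np.log(worth)[:, None] - np.log(worth[:, None] + worth[None, :]))
    return float(np.where(wins > 0, ll, 0.0).sum())


def fit_bt(
    wins: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 10000,
    pseudocount: float = 0.0,
) -> WorthVector:
    """Fit worth parameters by the MM/Zermelo fixed point.

    ``pseudocount`` is added to every ordered off-diagonal cell before
    fitting; the default 0 fails loudly on degenerate records (a stimulus
    with no wins or no losses) rather than silently regularizing.
    Convergence: maximum relative worth change below ``tol``.
    """
    labels = list(wins.index)
    W = np.asarray(wins, dtype=float).copy()
    n = len(labels)
    if W.shape != (n, n) or list(wins.columns) != labels:
        raise ValueError("win matrix must be square with matching row/column labels")
    if np.any(np.diag(W) != 0):
        raise ValueError("win matrix diagonal must be zero")
    if np.any(W < 0):
        raise ValueError("win counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount > 0:
        W = W + pseudocount * (1.0 - np.eye(n))

    n_ij = W + W.T
    n_comp, member = connected_components(n_ij > 0, directed=False)
    if n_comp > 1:
        comps = [
            [labels[i] for i in range(n) if member[i] == c] for c in range(n_comp)
        ]
        raise DisconnectedComparisonsError(comps)
    row_wins = W.sum(axis=1)
    col_losses = W.sum(axis=0)
    if np.any(row_wins == 0) or np.any(col_losses == 0):
        bad = [
            labels[i]
            for i in range(n)
            if row_wins[i] == 0 or col_losses[i] == 0
        ]
        raise DegenerateRecordError(
            "stimuli with all wins or all losses have divergent worths: "
            + ", ".join(map(str, bad))
            + "; pass a small pseudocount (e.g. 0.5) to regularize"
        )

    pi = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = (n_ij / (pi[:, None] + pi[None, :]))
        np.fill_diagonal(denom, 0.0)
        new_pi = row_wins / denom.sum(axis=1)
        new_pi /= new_pi.sum()
        if np.max(np.abs(new_pi - pi) / pi) < tol:
            pi = new_pi
            converged = True
            break
        pi = new_pi
    worth = pd.Series(pi, index=labels, name="worth")
    return WorthVector(
        worth=worth,
        log_worth=pd.Series(np.log(pi), index=labels, name="log_worth"),
        n_iter=it,
        converged=converged,
        log_likelihood=bt_log_likelihood(W, pi),
    )


def bt_scores_from_trials(
    seq: TrialSequence,
    tol: float = 1e-8,
    max_iter: int = 10000,
    pseudocount: float = 0.0,
) -> WorthVector:
    """Count wins from the trials, then fit; order of trials is irrelevant."""
    return fit_bt(count_wins(seq), tol=tol, max_iter=max_iter, pseudocount=pseudocount)
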