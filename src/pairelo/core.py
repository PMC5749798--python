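"""Sequential Elo scoring of forced-choice pairwise-comparison trials.

Each trial is a contest between two stimuli; the one chosen by the rater is
the winner.  Scores are updated sequentially: before a trial the current
scores imply a win probability under a logistic model,

    E_w = 1 / (1 + base^((S_l - S_w) / divisor)),

and after the trial the winner gains ``k * (O_w - E_w)`` points while the
loser loses exactly the same amount (``O_w`` is 1 for a decisive choice and
0.5 for a draw).  Point exchange is symmetric, so the mean score over a
fixed roster always equals the starting score.

The module exposes the primitive steps (:func:`expected_outcome`,
:func:`update_scores`), the sequential runner (:func:`run_sequence`), and a
vectorized multi-sequence runner used by the sequence-randomization layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EloConfig",
    "Trial",
    "TrialSequence",
    "UpsetRecord",
    "expected_outcome",
    "update_scores",
    "run_sequence",
]


@dataclass(frozen=True)
class EloConfig:
    """Parameters of the Elo update rule.

    k is the maximum number of points exchangeable in one trial (default
    100); start_score is the common initial score (default 0); the logistic
    base/divisor pair (default 10/400) sets the score scale: a divisor-point
    advantage corresponds to base-to-one predicted odds.
    """

    k: float = 100.0
    start_score: float = 0.0
    logistic_base: float = 10.0
    logistic_divisor: float = 400.0

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"k must be positive, got {self.k}")
        if not (self.logistic_base > 1):
            raise ValueError(f"logistic_base must exceed 1, got {self.logistic_base}")
        if not (self.logistic_divisor > 0):
            raise ValueError(
                f"logistic_divisor must be positive, got {self.logistic_divisor}"
            )
        if not math.isfinite(self.start_score):
            raise ValueError("start_score must be finite")


@dataclass(frozen=True)
class Trial:
    """One forced-choice judgement.

    ``winner``/``loser`` are the chosen and unchosen stimulus.  When
    ``draw`` is true no choice was made and the two fields merely label the
    first and second member of the pair.
    """

    rater: str
    order: int
    winner: str
    loser: str
    draw: bool = False

    def __post_init__(self) -> None:
        if self.winner == self.loser:
            raise ValueError(
                f"trial pits stimulus {self.winner!r} against itself"
            )
        if self.order < 0:
            raise ValueError(f"order must be non-negative, got {self.order}")


@dataclass(frozen=True)
class UpsetRecord:
    """Per-trial expectation bookkeeping for the consistency indices.

    ``had_expectation`` is true when the pre-update score difference was
    nonzero and the trial was decisive; ``upset`` marks a win by the
    lower-scored member; ``weight`` is the absolute pre-update score
    difference (zero exactly when no expectation existed).
    """

    trial_index: int
    had_expectation: bool
    upset: bool
    weight: float


class TrialSequence:
    """An ordered list of trials over a fixed stimulus roster.

    The list order is the processing order.  The roster defaults to the
    sorted union of stimuli appearing in the trials; an explicit roster may
    include stimuli never compared (they keep the start score).
    """

    def __init__(
        self,
        trials: Iterable[Trial],
        roster: Iterable[str] | None = None,
    ) -> None:
        self.trials: tuple[Trial, ...] = tuple(trials)
        seen = {t.winner for t in self.trials} | {t.loser for t in self.trials}
        if roster is None:
            self.roster: tuple[str, ...] = tuple(sorted(seen))
        else:
            self.roster = tuple(dict.fromkeys(roster))
            missing = seen - set(self.roster)
            if missing:
                raise ValueError(
                    "trials reference stimuli outside the roster: "
                    + ", ".join(sorted(map(str, missing)))
                )
        self._index = {s: i for i, s in enumerate(self.roster)}
        self._encoded: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def raters(self) -> tuple[str, ...]:
        """Raters in order of first appearance in the sequence."""
        return tuple(dict.fromkeys(t.rater for t in self.trials))

    def encoded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Integer-coded (winner, loser, draw) arrays, cached."""
        if self._encoded is None:
            w = np.fromiter(
                (self._index[t.winner] for t in self.trials), dtype=np.intp,
                count=len(self.trials),
            )
            l = np.fromiter(
                (self._index[t.loser] for t in self.trials), dtype=np.intp,
                count=len(self.trials),
            )
            d = np.fromiter(
                (t.draw for t in self.trials), dtype=bool, count=len(self.trials)
            )
            self._encoded = (w, l, d)
        return self._encoded

    def subset_raters(self, raters: Sequence[str]) -> "TrialSequence":
        """Trials of the given raters, original order and roster preserved."""
        keep = set(raters)
        return TrialSequence(
            (t for t in self.trials if t.rater in keep), roster=self.roster
        )


def expected_outcome(
    score_a: float, score_b: float, config: EloConfig = EloConfig()
) -> tuple[float, float]:
    """Predicted win probabilities (E_a, E_b) for the two current scores.

    E_a = 1 / (1 + base^((score_b - score_a)/divisor)); the pair sums to 1
    exactly and swapping the arguments swaps the pair.
    """
    if not (math.isfinite(score_a) and math.isfinite(score_b)):
        raise ValueError("scores must be finite")
    e_a = 1.0 / (
        1.0
        + config.logistic_base ** ((score_b - score_a) / config.logistic_divisor)
    )
    return e_a, 1.0 - e_a


def update_scores(
    score_w: float,
    score_l: float,
    outcome_w: float = 1.0,
    config: EloConfig = EloConfig(),
) -> tuple[float, float]:
    """Post-trial scores (new_w, new_l) for the winner and loser.

    ``outcome_w`` is 1 for a decisive win by the first member, 0.5 for a
    draw.  The exchange is symmetric, so the pair sum is conserved exactly.
    """
    if outcome_w not in (1.0, 0.5, 1):
        raise ValueError(f"outcome must be 1 (win) or 0.5 (draw), got {outcome_w}")
    e_w, _ = expected_outcome(score_w, score_l, config)
    delta = config.k * (outcome_w - e_w)
    return score_w + delta, score_l - delta


def run_sequence(
    seq: TrialSequence,
    config: EloConfig = EloConfig(),
    with_trajectory: bool = False,
):
    """Run the Elo updates over the sequence in order.

    Returns the final scores as a Series indexed by the roster; with
    ``with_trajectory`` also returns the per-trial :class:`UpsetRecord`
    list used by the consistency indices.
    """
    base = config.logistic_base
    div = config.logistic_divisor
    k = config.k
    scores = [config.start_score] * len(seq.roster)
    w_idx, l_idx, draws = seq.encoded()
    records: list[UpsetRecord] = []
    for t in range(len(seq)):
        i = w_idx[t]
        j = l_idx[t]
        s_w = scores[i]
        s_l = scores[j]
        e_w = 1.0 / (1.0 + base ** ((s_l - s_w) / div))
        o_w = 0.5 if draws[t] else 1.0
        delta = k * (o_w - e_w)
        scores[i] = s_w + delta
        scores[j] = s_l - delta
        if with_trajectory:
            diff = s_w - s_l
            decisive = not draws[t]
            records.append(
                UpsetRecord(
                    trial_index=t,
                    had_expectation=decisive and diff != 0,
                    upset=decisive and diff < 0,
                    weight=abs(diff) if decisive and diff != 0 else 0.0,
                )
            )
    table = pd.Series(scores, index=list(seq.roster), name="elo", dtype=float)
    if with_trajectory:
        return table, records
    return table


def batch_run(
    seq: TrialSequence,
    config: EloConfig,
    perms: np.ndarray,
    track_consistency: bool = False,
):
    """Run the Elo updates under many trial orderings at once.

    ``perms`` has one row per sequence, each a permutation of
    ``range(len(seq))``.  Returns the final-score matrix (sequence x
    stimulus); with ``track_consistency`` also a dict of per-sequence
    arrays ``n_expected``, ``n_upsets``, ``sum_weights`` (over expectation
    trials) and ``sum_upset_weights``.

    The scores matrix is updated one trial position at a time with the same
    arithmetic as :func:`run_sequence`; all sequences advance in lockstep.
    """
    w_idx, l_idx, draws = seq.encoded()
    perms = np.asarray(perms, dtype=np.intp)
    n_seq, n_trials = perms.shape
    if n_trials != len(seq):
        raise ValueError("permutation length does not match trial count")
    W = w_idx[perms]
    L = l_idx[perms]
    D = draws[perms]
    base = config.logistic_base
    div = config.logistic_divisor
    k = config.k
    scores = np.full((n_seq, len(seq.roster)), config.start_score, dtype=float)
    rows = np.arange(n_seq)
    if track_consistency:
        n_expected = np.zeros(n_seq, dtype=np.int64)
        n_upsets = np.zeros(n_seq, dtype=np.int64)
        sum_weights = np.zeros(n_seq, dtype=float)
        sum_upset_weights = np.zeros(n_seq, dtype=float)
    for t in range(n_trials):
        wi = W[:, t]
        li = L[:, t]
        s_w = scores[rows, wi]
        s_l = scores[rows, li]
        diff = s_w - s_l
        e_w = 1.0 / (1.0 + base ** (-diff / div))
        o_w = np.where(D[:, t], 0.5, 1.0)
        delta = k * (o_w - e_w)
        scores[rows, wi] = s_w + delta
        scores[rows, li] = s_l - delta
        if track_consistency:
            decisive = ~D[:, t]
            expect = decisive & (diff != 0)
            upset = decisive & (diff < 0)
            wgt = np.abs(diff)
            n_expected += expect
            n_upsets += upset
            sum_weights += np.where(expect, wgt, 0.0)
            sum_upset_weights += np.where(upset, wgt, 0.0)
    if track_consistency:
        return scores, {
            "n_expected": n_expected,
            "n_upsets": n_upsets,
            "sum_weights": sum_weights,
            "sum_upset_weights": sum_upset_weights,
        }
    return scores
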