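"""Sequence-randomized mean Elo (mElo).

Final Elo scores depend on the order in which trials are processed, but for
static stimuli the presentation order carries no information — it is pure
noise.  mElo removes it by re-running the Elo updates over many random
permutations of the pooled trial list and averaging the final scores per
stimulus.  One hundred sequences (the original plus 99 shuffles) is the
default; going to 1000 changes essentially nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .core import EloConfig, TrialSequence, batch_run

__all__ = ["RandomizationPlan", "MeloResult", "randomize_sequence", "melo_scores"]

#: Trial-count ceiling for exhaustive permutation enumeration (8! = 40320).
EXHAUSTIVE_LIMIT = 8


@dataclass(frozen=True)
class RandomizationPlan:
    """How many trial orderings to evaluate and how to generate them.

    ``include_original`` counts the as-presented order as sequence 1.  With
    ``exhaustive`` and at most :data:`EXHAUSTIVE_LIMIT` trials, every
    permutation is enumerated instead of sampling (``n_sequences`` and the
    seed are then ignored).  Sampled permutations are drawn independently,
    so repeats are possible; immaterial when n_sequences << (trial count)!.
    """

    n_sequences: int = 100
    include_original: bool = True
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError(
                f"n_sequences must be at least 1, got {self.n_sequences}"
            )


@dataclass(frozen=True)
class MeloResult:
    """Mean Elo scores with per-sequence detail.

    ``melo`` is the row mean of ``per_sequence`` (stimulus x sequence);
    ``elo_original`` is the original-order column when the plan included
    it; ``dispersion`` holds per-stimulus min, max and IQR across
    sequences.
    """

    melo: pd.Series
    elo_original: pd.Series | None
    per_sequence: pd.DataFrame
    dispersion: pd.DataFrame

    @property
    def n_sequences(self) -> int:
        return self.per_sequence.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Summary table, one row per stimulus, sorted by descending mElo."""
        out = pd.DataFrame({"melo": self.melo})
        out["elo_original"] = (
            self.elo_original if self.elo_original is not None else np.nan
        )
        out = out.join(self.dispersion)
        out.index.name = "stimulus"
        return out.sort_values("melo", ascending=False)


def randomize_sequence(
    seq: TrialSequence, rng: np.random.Generator
) -> TrialSequence:
    """Uniformly random permutation of the pooled trial list.

    Trials from all raters are shuffled together; trial contents (pairing,
    outcome) are unchanged.
    """
    perm = rng.permutation(len(seq))
    return TrialSequence((seq.trials[i] for i in perm), roster=seq.roster)


def plan_permutations(plan: RandomizationPlan, n_trials: int) -> np.ndarray:
    """Materialize the plan as a (sequence x trial) permutation matrix.

    Row 0 is the identity (original order) when the plan includes it.  One
    child generator is spawned per sampled sequence from the master seed,
    so any subset of rows is reproducible independently of evaluation
    order.
    """
    if plan.exhaustive and n_trials <= EXHAUSTIVE_LIMIT:
        return np.array(
            list(permutations(range(n_trials))), dtype=np.intp
        ).reshape(math.factorial(n_trials), n_trials)
    rows = []
    n_random = plan.n_sequences - (1 if plan.include_original else 0)
    if plan.include_original:
        rows.append(np.arange(n_trials, dtype=np.intp))
    if n_random > 0:
        children = np.random.SeedSequence(plan.seed).spawn(n_random)
        for child in children:
            rng = np.random.default_rng(child)
            rows.append(rng.permutation(n_trials).astype(np.intp))
    return np.vstack(rows) if rows else np.empty((0, n_trials), dtype=np.intp)


def melo_scores(
    seq: TrialSequence,
    config: EloConfig = EloConfig(),
    plan: RandomizationPlan = RandomizationPlan(),
) -> MeloResult:
    """Average final Elo scores over the plan's trial orderings."""
    if len(seq) == 0:
        raise ValueError("cannot compute mElo for an empty trial list")
    perms = plan_permutations(plan, len(seq))
    scores = batch_run(seq, config, perms)  # (n_seq, n_stim)
    index = list(seq.roster)
    per_sequence = pd.DataFrame(
        scores.T, index=index,
        columns=[f"seq_{i}" for i in range(scores.shape[0])],
    )
    melo = pd.Series(scores.mean(axis=0), index=index, name="melo")
    original = None
    if plan.include_original and not (
        plan.exhaustive and len(seq) <= EXHAUSTIVE_LIMIT
    ):
        original = pd.Series(scores[0], index=index, name="elo_original")
    q75 = np.percentile(scores, 75, axis=0)
    q25 = np.percentile(scores, 25, axis=0)
    dispersion = pd.DataFrame(
        {
            "min": scores.min(axis=0),
            "max": scores.max(axis=0),
            "iqr": q75 - q25,
        },
        index=index,
    )
    return MeloResult(
        melo=melo, elo_original=original,
        per_sequence=per_sequence, dispersion=dispersion,
    )
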