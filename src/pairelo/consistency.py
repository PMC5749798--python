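"""Upset-based consistency indices for pairwise-comparison sequences.

Each trial whose members enter with unequal Elo scores carries an
expectation: the higher-scored member should be chosen.  A choice of the
lower-scored member is an upset.  Over the N expectation-bearing trials of
a sequence the unweighted index is

    R = 1 - (number of upsets) / N,

and the weighted variant discounts upsets by the score gap they violated,

    R' = 1 - (sum of upset gaps) / (sum of all gaps),

i.e. the proportion of all points at stake that were correctly predicted.
Both lie in [0, 1]; 0.5 corresponds to random choice (values below 0.5 are
possible).  Draws update scores but carry no expectation, and trials with a
zero score difference are excluded from N entirely.  Averaging the indices
over randomized trial orderings gives a sequence-noise-free summary, the
counterpart of mElo; indices are conceptually, but not numerically,
comparable to an ICC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EloConfig, TrialSequence, UpsetRecord, batch_run, run_sequence
from .melo import RandomizationPlan, plan_permutations

__all__ = [
    "ConsistencyResult",
    "MeanConsistencyResult",
    "consistency_indices",
    "mean_consistency",
    "rater_accumulation",
]


@dataclass(frozen=True)
class ConsistencyResult:
    """Consistency indices for one trial ordering.

    When no trial carried an expectation (``n_expected == 0``) the indices
    are undefined and ``R``/``R_weighted`` are None — an explicit sentinel
    rather than a silent 0 or 1.
    """

    R: float | None
    R_weighted: float | None
    n_expected: int
    n_upsets: int
    records: tuple[UpsetRecord, ...] = ()

    @property
    def has_expectation(self) -> bool:
        return self.n_expected > 0


@dataclass(frozen=True)
class MeanConsistencyResult:
    """Across-sequence mean indices under a randomization plan.

    Sequences with no expectation-bearing trial are excluded from the
    means and counted in ``n_excluded``.  ``per_sequence`` has one row per
    ordering with columns R, R_weighted, n_expected, n_upsets.
    """

    mean_R: float | None
    mean_R_weighted: float | None
    original_R: float | None
    original_R_weighted: float | None
    per_sequence: pd.DataFrame
    n_sequences: int
    n_excluded: int


def _indices_from_counts(
    n_expected: int, n_upsets: int, sum_weights: float, sum_upset_weights: float
) -> tuple[float | None, float | None]:
    if n_expected == 0:
        return None, None
    return (
        1.0 - n_upsets / n_expected,
        1.0 - sum_upset_weights / sum_weights,
    )


def consistency_indices(
    seq: TrialSequence, config: EloConfig = EloConfig()
) -> ConsistencyResult:
    """Compute R and R' for the sequence in its given order."""
    _, records = run_sequence(seq, config, with_trajectory=True)
    n_expected = sum(r.had_expectation for r in records)
    n_upsets = sum(r.upset for r in records)
    sum_w = sum(r.weight for r in records)
    sum_uw = sum(r.weight for r in records if r.upset)
    R, Rw = _indices_from_counts(n_expected, n_upsets, sum_w, sum_uw)
    return ConsistencyResult(
        R=R, R_weighted=Rw, n_expected=n_expected, n_upsets=n_upsets,
        records=tuple(records),
    )


def mean_consistency(
    seq: TrialSequence,
    config: EloConfig = EloConfig(),
    plan: RandomizationPlan = RandomizationPlan(),
) -> MeanConsistencyResult:
    """Average R and R' over the plan's trial orderings.

    Uses the same permutation plan as :func:`pairelo.melo.melo_scores`, so
    a shared seed yields indices for exactly the orderings that produced
    the mElo scores.
    """
    if len(seq) == 0:
        raise ValueError("cannot compute consistency for an empty trial list")
    perms = plan_permutations(plan, len(seq))
    _, stats = batch_run(seq, config, perms, track_consistency=True)
    n_exp = stats["n_expected"]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = 1.0 - stats["n_upsets"] / n_exp
        Rw = 1.0 - stats["sum_upset_weights"] / stats["sum_weights"]
    valid = n_exp > 0
    per_sequence = pd.DataFrame(
        {
            "R": np.where(valid, R, np.nan),
            "R_weighted": np.where(valid, Rw, np.nan),
            "n_expected": n_exp,
            "n_upsets": stats["n_upsets"],
        }
    )
    has_original = plan.include_original and not (
        plan.exhaustive and len(seq) <= 8
    )
    return MeanConsistencyResult(
        mean_R=float(R[valid].mean()) if valid.any() else None,
        mean_R_weighted=float(Rw[valid].mean()) if valid.any() else None,
        original_R=float(R[0]) if has_original and valid[0] else None,
        original_R_weighted=float(Rw[0]) if has_original and valid[0] else None,
        per_sequence=per_sequence,
        n_sequences=len(perms),
        n_excluded=int((~valid).sum()),
    )


def rater_accumulation(
    seq: TrialSequence,
    config: EloConfig = EloConfig(),
    plan: RandomizationPlan = RandomizationPlan(),
    step: int = 1,
) -> pd.DataFrame:
    """Stability curve of the weighted index as raters accumulate.

    Raters are taken in order of first appearance in the original
    sequence; prefix r uses all trials of the first r raters.  Returns one
    row per prefix size (1 to all raters in increments of ``step``; the
    full panel is always the last row) with the across-sequence mean of
    R', the original-order R', and the across-sequence IQR bounds.  The
    curve typically rises then plateaus; the plateau onset indicates how
    many raters are needed for stable indices.
    """
    if step < 1:
        raise ValueError(f"step must be positive, got {step}")
    raters = seq.raters
    if not raters:
        raise ValueError("trial list is empty; no raters to accumulate")
    sizes = list(range(1, len(raters) + 1, step))
    if sizes[-1] != len(raters):
        sizes.append(len(raters))
    rows = []
    for r in sizes:
        sub = seq.subset_raters(raters[:r])
        res = mean_consistency(sub, config, plan)
        rw = res.per_sequence["R_weighted"].dropna()
        iqr_lo, iqr_hi = (
            (float(rw.quantile(0.25)), float(rw.quantile(0.75)))
            if len(rw)
            else (np.nan, np.nan)
        )
        rows.append(
            {
                "raters": r,
                "n_trials": len(sub),
                "mean_R": res.mean_R,
                "mean_Rw": res.mean_R_weighted,
                "original_Rw": res.original_R_weighted,
                "iqr_lo": iqr_lo,
                "iqr_hi": iqr_hi,
                "excluded": res.n_excluded,
            }
        )
    return pd.DataFrame(rows)
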