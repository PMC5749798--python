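"""Synthetic rating-experiment generator.

Emulates the design of a two-task rating study: N stimuli, each carrying a
latent strength theta ~ Normal(0, sigma_theta) on the Elo scale, are (a)
rated once per rater on a bounded integer (Likert) scale and (b) compared
pairwise in B blocks per rater, each block a uniformly random perfect
matching of the stimulus set presented in random order.  Pairwise choices
follow the same logistic law as the Elo expectation,

    P(i chosen over j) = 1 / (1 + 10^(-(theta_i - theta_j) / s)),

so the choice scale ``s`` has a direct Elo-scale meaning (smaller s = more
deterministic raters).  Likert responses discretize a noisy percept
``theta + rater bias + noise`` through equal-population thresholds; the
rater bias deliberately affects only the Likert task — pairwise choices
depend on score differences, so additive rater offsets cancel there.

Defaults mirror an 82-stimulus, 56-rater, 2-block design (41 pairs per
block, 82 comparisons per rater).  Setting ``latent_sd = 0`` turns every
choice into a fair coin flip, the canonical null panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trial, TrialSequence

__all__ = [
    "SimConfig",
    "SyntheticPanel",
    "simulate_latent",
    "simulate_pairings",
    "simulate_choices",
    "simulate_likert",
    "simulate_panel",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generative parameters.

    latent_sd (sigma_theta) is the SD of true strengths on the Elo scale;
    choice_scale (s) is the logistic divisor of the choice model;
    rater_bias_sd and noise_sd are the SDs of the per-rater additive
    offset and the per-response perceptual noise entering the Likert task
    (same Elo-scale units as theta).
    """

    n_stimuli: int = 82
    n_raters: int = 56
    n_blocks: int = 2
    latent_sd: float = 200.0
    choice_scale: float = 300.0
    likert_levels: int = 7
    rater_bias_sd: float = 60.0
    noise_sd: float = 120.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise ValueError(f"need at least 2 stimuli, got {self.n_stimuli}")
        if self.n_raters < 1 or self.n_blocks < 1:
            raise ValueError("need at least one rater and one block")
        if self.choice_scale <= 0:
            raise ValueError("choice_scale must be positive")
        if min(self.latent_sd, self.rater_bias_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.likert_levels < 2:
            raise ValueError("need at least 2 Likert levels")

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(f"S{i:03d}" for i in range(1, self.n_stimuli + 1))

    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(f"R{i:03d}" for i in range(1, self.n_raters + 1))


@dataclass(frozen=True)
class SyntheticPanel:
    """A complete simulated study: ground truth, trials and ratings."""

    latent: pd.Series
    trials: TrialSequence
    ratings: pd.DataFrame
    config: SimConfig


def simulate_latent(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """True strengths theta ~ iid Normal(0, latent_sd), one per stimulus."""
    theta = rng.normal(0.0, config.latent_sd, size=config.n_stimuli)
    return pd.Series(theta, index=list(config.stimuli), name="theta")


def simulate_pairings(
    config: SimConfig, rng: np.random.Generator
) -> list[list[list[tuple[str, str]]]]:
    """Random perfect matchings: pairings[rater][block] is a list of pairs.

    Each matching is generated by shuffling the roster and pairing
    adjacent elements, which is uniform over perfect matchings; the
    resulting pair list is already in random presentation order.  With an
    odd roster one stimulus sits out per block, rotated across the blocks
    of the study so no stimulus is systematically under-compared.
    """
    stimuli = list(config.stimuli)
    n = len(stimuli)
    out: list[list[list[tuple[str, str]]]] = []
    block_counter = 0
    for _ in range(config.n_raters):
        rater_blocks: list[list[tuple[str, str]]] = []
        for _ in range(config.n_blocks):
            pool = stimuli
            if n % 2 == 1:
                sit_out = stimuli[block_counter % n]
                pool = [s for s in stimuli if s != sit_out]
            order = rng.permutation(len(pool))
            shuffled = [pool[i] for i in order]
            pairs = [
                (shuffled[i], shuffled[i + 1]) for i in range(0, len(shuffled), 2)
            ]
            rater_blocks.append(pairs)
            block_counter += 1
        out.append(rater_blocks)
    return out


def simulate_choices(
    pairings: list[list[list[tuple[str, str]]]],
    latent: pd.Series,
    config: SimConfig,
    rng: np.random.Generator,
) -> TrialSequence:
    """Logistic forced choices over the pairings, in presentation order.

    Trials are emitted rater by rater, block by block, forming the
    "original sequence"; ``order`` is the within-rater trial number.
    """
    theta = latent.to_dict()
    s = config.choice_scale
    trials: list[Trial] = []
    for rater_label, rater_blocks in zip(config.raters, pairings):
        order = 0
        for pairs in rater_blocks:
            for a, b in pairs:
                # clamp the exponent so a near-deterministic scale (s -> 0)
                # saturates at p = 0/1 instead of overflowing
                z = min(max(-(theta[a] - theta[b]) / s, -300.0), 300.0)
                p_a = 1.0 / (1.0 + 10.0**z)
                if rng.random() < p_a:
                    winner, loser = a, b
                else:
                    winner, loser = b, a
                trials.append(
                    Trial(rater=rater_label, order=order, winner=winner, loser=loser)
                )
                order += 1
    return TrialSequence(trials, roster=config.stimuli)


def simulate_likert(
    latent: pd.Series, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Integer ratings (stimuli x raters) from a discretized noisy percept.

    percept = theta + rater bias + response noise; the pooled percept
    sample is cut at its own equal-population quantiles into
    ``likert_levels`` bins, giving an approximately uniform marginal use
    of the scale.
    """
    n, k = config.n_stimuli, config.n_raters
    bias = rng.normal(0.0, config.rater_bias_sd, size=k)
    noise = rng.normal(0.0, config.noise_sd, size=(n, k))
    percept = latent.to_numpy()[:, None] + bias[None, :] + noise
    qs = np.arange(1, config.likert_levels) / config.likert_levels
    thresholds = np.quantile(percept, qs)
    ratings = np.digitize(percept, thresholds) + 1
    return pd.DataFrame(
        ratings, index=list(config.stimuli), columns=list(config.raters),
        dtype=int,
    )


def simulate_panel(config: SimConfig) -> SyntheticPanel:
    """Generate a full study panel reproducibly from ``config.seed``.

    Independent child generators drive the latent draw, the pairings, the
    choices and the Likert task, so e.g. the latent vector is unchanged if
    only the number of blocks changes.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_pair, rng_choice, rng_likert = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    latent = simulate_latent(config, rng_latent)
    pairings = simulate_pairings(config, rng_pair)
    trials = simulate_choices(pairings, latent, config, rng_choice)
    ratings = simulate_likert(latent, config, rng_likert)
    return SyntheticPanel(
        latent=latent, trials=trials, ratings=ratings, config=config
    )
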