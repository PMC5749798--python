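import pytest

from pairelo import SimConfig, Trial, TrialSequence, simulate_panel


def make_trials(spec_list):
    """Build a TrialSequence from (winner, loser[, draw]) tuples, one rater."""
    trials = []
    for i, item in enumerate(spec_list):
        w, l, *rest = item
        trials.append(
            Trial(rater="r1", order=i, winner=w, loser=l, draw=bool(rest and rest[0]))
        )
    return TrialSequence(trials)


def random_trials(rng, n_trials, stimuli=("A", "B", "C", "D"), n_raters=2,
                  p_draw=0.0):
    """Random trial sequence for oracle-equivalence checks."""
    trials = []
    for i in range(n_trials):
        w, l = rng.choice(len(stimuli), size=2, replace=False)
        trials.append(
            Trial(
                rater=f"r{rng.integers(n_raters) + 1}",
                order=i,
                winner=stimuli[w],
                loser=stimuli[l],
                draw=bool(rng.random() < p_draw),
            )
        )
    return TrialSequence(trials, roster=stimuli)


@pytest.fixture(scope="session")
def small_panel():
    """A quick 20-stimulus, 12-rater study for structural tests."""
    return simulate_panel(SimConfig(n_stimuli=20, n_raters=12, seed=7))


@pytest.fixture(scope="session")
def default_panel():
    """The full default study design (82 stimuli, 56 raters, 2 blocks)."""
    return simulate_panel(SimConfig(seed=0))
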