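import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairelo import (
    EloConfig,
    Trial,
    TrialSequence,
    expected_outcome,
    run_sequence,
    update_scores,
)
from pairelo.core import batch_run

from conftest import make_trials, random_trials
from oracles import elo_oracle


class TestExpectedOutcome:
    @pytest.mark.parametrize(
        "sa, sb, ea",
        [
            (0, 0, 0.5),
            (400, 0, 10 / 11),
            (-400, 400, 1 / 101),
        ],
    )
    def test_logistic_win_probability(self, sa, sb, ea):
        e_a, e_b = expected_outcome(sa, sb)
        assert e_a == pytest.approx(ea, abs=1e-9)
        assert e_a + e_b == pytest.approx(1.0, abs=1e-12)

    def test_swapping_scores_swaps_probabilities(self):
        e_a, e_b = expected_outcome(123.0, -77.0)
        e_b2, e_a2 = expected_outcome(-77.0, 123.0)
        assert e_a == pytest.approx(e_a2, abs=1e-12)
        assert e_b == pytest.approx(e_b2, abs=1e-12)

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_non_finite_score_rejected(self, bad):
        with pytest.raises(ValueError):
            expected_outcome(bad, 0.0)


class TestUpdateScores:
    @pytest.mark.parametrize(
        "sw, sl, outcome, expect",
        [
            (0, 0, 1.0, (50, -50)),
            (400, 0, 1.0, (400 + 100 / 11, -100 / 11)),
            (0, 0, 0.5, (0, 0)),
        ],
    )
    def test_point_exchange(self, sw, sl, outcome, expect):
        new = update_scores(sw, sl, outcome)
        assert new == pytest.approx(expect, abs=1e-6)

    def test_invalid_outcome_rejected(self):
        with pytest.raises(ValueError):
            update_scores(0, 0, 0.7)

    @given(
        sw=st.floats(-2000, 2000),
        sl=st.floats(-2000, 2000),
        outcome=st.sampled_from([1.0, 0.5]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_conservation_and_surprise_scaling(self, sw, sl, outcome):
        new_w, new_l = update_scores(sw, sl, outcome)
        assert new_w + new_l == pytest.approx(sw + sl, rel=1e-9, abs=1e-9)
        if outcome == 1.0:
            # an expected win moves fewer points than an upset of equal gap
            gain = new_w - sw
            upset_gain = update_scores(sl, sw, 1.0)[0] - sl
            if sw - sl > 1e-3:  # gap large enough to resolve in floats
                assert gain < upset_gain
            assert 0 < gain < EloConfig().k


class TestRunSequence:
    def test_empty_sequence_keeps_start_scores(self):
        seq = TrialSequence([], roster=("A", "B"))
        scores = run_sequence(seq, EloConfig(start_score=12.5))
        assert list(scores) == [12.5, 12.5]

    def test_single_trial_transfers_half_k(self):
        scores = run_sequence(make_trials([("A", "B")]))
        assert scores["A"] == pytest.approx(50)
        assert scores["B"] == pytest.approx(-50)

    def test_three_trial_hand_example(self):
        # A>B, B>C, A>C with k=100, start 0, worked by hand through the
        # update formulas (intermediate after trial 2: B=7.146, C=-57.146)
        scores = run_sequence(make_trials([("A", "B"), ("B", "C"), ("A", "C")]))
        assert scores["A"] == pytest.approx(85.05, abs=0.01)
        assert scores["B"] == pytest.approx(7.15, abs=0.01)
        assert scores["C"] == pytest.approx(-92.20, abs=0.01)
        assert scores.sum() == pytest.approx(0, abs=1e-9)

    def test_stimulus_outside_roster_rejected(self):
        with pytest.raises(ValueError, match="outside the roster"):
            TrialSequence([Trial("r1", 0, "A", "X")], roster=("A", "B"))

    def test_self_contest_rejected(self):
        with pytest.raises(ValueError):
            Trial("r1", 0, "A", "A")

    def test_repeated_wins_move_scores_monotonically(self):
        prev_a, prev_b = 0.0, 0.0
        for n in range(1, 8):
            scores = run_sequence(make_trials([("A", "B")] * n))
            assert scores["A"] > prev_a
            assert scores["B"] < prev_b
            prev_a, prev_b = scores["A"], scores["B"]

    def test_relabeling_permutes_scores(self):
        spec = [("A", "B"), ("B", "C"), ("A", "C"), ("C", "B")]
        relabel = {"A": "Z", "B": "Y", "C": "X"}
        scores = run_sequence(make_trials(spec))
        swapped = run_sequence(
            make_trials([(relabel[w], relabel[l]) for w, l in spec])
        )
        for orig, new in relabel.items():
            assert scores[orig] == swapped[new]

    @pytest.mark.parametrize("trial_seed", range(10))
    def test_matches_literal_formula_transcription(self, trial_seed):
        rng = np.random.default_rng(trial_seed)
        seq = random_trials(rng, 10, p_draw=0.2)
        expected = elo_oracle([(t.winner, t.loser, t.draw) for t in seq])
        scores = run_sequence(seq)
        for s, v in expected.items():
            assert scores[s] == pytest.approx(v, abs=1e-9)

    def test_draws_conserve_and_pull_scores_together(self):
        seq = make_trials([("A", "B"), ("A", "B", True)])
        scores = run_sequence(seq)
        # the draw moves the leader back toward the trailer
        assert 0 < scores["A"] < 50
        assert scores.sum() == pytest.approx(0, abs=1e-12)


class TestBatchRunner:
    def test_batch_rows_equal_single_sequence_runs(self):
        rng = np.random.default_rng(3)
        seq = random_trials(rng, 30, stimuli=tuple("ABCDEF"), p_draw=0.1)
        perms = np.vstack([rng.permutation(30) for _ in range(5)])
        batch = batch_run(seq, EloConfig(), perms)
        for row, perm in zip(batch, perms):
            reordered = TrialSequence(
                (seq.trials[i] for i in perm), roster=seq.roster
            )
            single = run_sequence(reordered)
            np.testing.assert_allclose(row, single.to_numpy(), atol=1e-9)

    def test_batch_consistency_counters_match_trajectory(self):
        rng = np.random.default_rng(4)
        seq = random_trials(rng, 25, p_draw=0.15)
        perm = rng.permutation(25)
        _, stats = batch_run(seq, EloConfig(), perm[None, :], track_consistency=True)
        reordered = TrialSequence((seq.trials[i] for i in perm), roster=seq.roster)
        _, records = run_sequence(reordered, with_trajectory=True)
        assert stats["n_expected"][0] == sum(r.had_expectation for r in records)
        assert stats["n_upsets"][0] == sum(r.upset for r in records)
        assert stats["sum_weights"][0] == pytest.approx(
            sum(r.weight for r in records)
        )
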