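"""Sequential Elo scoring of a handful of forced-choice trials.

Builds a three-trial sequence by hand, runs the sequential update rule and
prints the score trajectory logic: the winner of each trial takes points
from the loser in proportion to how surprising the win was.
"""

from pairelo import EloConfig, Trial, TrialSequence, expected_outcome, run_sequence

trials = [
    Trial(rater="r1", order=0, winner="A", loser="B"),
    Trial(rater="r1", order=1, winner="B", loser="C"),
    Trial(rater="r1", order=2, winner="A", loser="C"),
]
seq = TrialSequence(trials)

e_a, e_b = expected_outcome(400, 0)
print(f"win probability at a 400-point advantage: {e_a:.3f} vs {e_b:.3f}")

scores = run_sequence(seq, EloConfig(k=100, start_score=0))
print("\nfinal scores after A>B, B>C, A>C (k=100, start 0):")
print(scores.round(2).to_string())
print(f"mean score: {scores.mean():.2e}  (point exchange is symmetric,")
print("so the mean always equals the starting score)")
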