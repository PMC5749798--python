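# pairelo

Score perceived characteristics of a stimulus set — attractiveness,
strength, dominance, any judgement a rater can make — from **forced-choice
pairwise comparisons**, as an alternative to single-stimulus Likert rating.
The package is aimed at psychologists, psychophysicists and behavioural
ecologists who collect "which of these two is more X?" trials and want an
interval-scale score per stimulus, together with the statistics needed to
validate that score against other measures.

## The methods

**Elo rating.** Each trial is a contest.  With current scores
*S*₁, *S*₂ the first member's win probability is modelled as

    E₁ = 1 / (1 + 10^((S₂ − S₁)/400)),

and after the trial scores update as *S*′ = *S* + *k*(*O* − *E*) with
outcome *O* ∈ {1, 0, 0.5} and maximum point exchange *k* (default 100; all
stimuli start at 0).  The winner's gain equals the loser's loss, so the
mean score always equals the start score.

**mElo.** For static stimuli the order of trials is pure noise: the same
outcomes processed in a different order give different final scores.  mElo
removes this by averaging final Elo scores over many random permutations
of the pooled trial list (default 100, the original order included; going
to 1000 changes essentially nothing).

**Consistency indices.** A trial whose members enter with unequal scores
carries an expectation; a win by the lower-scored member is an *upset*.
Over the *N* expectation-bearing trials

    R  = 1 − (Σ uᵢ)/N,          R′ = 1 − (Σ uᵢwᵢ)/(Σ wᵢ),

with *u* the upset indicator and *w* the absolute pre-trial score
difference.  Both lie in [0, 1]; 0.5 corresponds to random choice, and R′
is the fraction of all points at stake whose direction was correctly
predicted.  These are conceptually — not numerically — comparable to an
ICC.

**Cross-validation.** A Bradley–Terry model (P(i beats j) =
πᵢ/(πᵢ+πⱼ), fit by the Zermelo/MM fixed point) provides an order-free
maximum-likelihood reference; mean Likert scores with the two-way
consistency ICC (average measures) and Williams's t (df = n − 3) cover the
rating-task side.  A study simulator generates complete synthetic panels
(latent strengths, random perfect-matching blocks, logistic choices,
discretized Likert percepts) so every pipeline can be exercised end to end
with known ground truth.

## A worked example

```python
from pairelo import (SimConfig, RandomizationPlan, simulate_panel,
                     melo_scores, mean_consistency, bt_scores_from_trials,
                     pearson)

panel = simulate_panel(SimConfig(seed=0))        # 82 stimuli, 56 raters, 2 blocks
melo  = melo_scores(panel.trials, plan=RandomizationPlan(seed=1)).melo
cons  = mean_consistency(panel.trials, plan=RandomizationPlan(seed=1))
bt    = bt_scores_from_trials(panel.trials)

print(round(pearson(melo, bt.log_worth.reindex(melo.index).to_numpy()), 4))
print(round(cons.mean_R, 3), round(cons.mean_R_weighted, 3))
```

prints

```
0.9992
0.747 0.852
```

— the mElo scores and the log Bradley–Terry worths agree almost perfectly
(r = 0.9992) because both summarize the same win/loss record, and about
75% of trial outcomes (85% of points at stake) went the way the preceding
scores predicted, i.e. raters in this simulated panel share perceptions
well above chance.  The same analyses run from the shell:

```sh
pairelo simulate --stimuli 82 --raters 56 --seed 0 --out study/
pairelo melo study/trials.csv --sequences 100 --seed 1 --out melo.csv
pairelo consistency study/trials.csv --sequences 100 --seed 1
pairelo pipeline study/trials.csv --ratings study/ratings.csv --seed 1 --out results/
```

Short narrative scripts for each capability live in `examples/`.

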