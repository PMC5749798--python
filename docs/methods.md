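# Methods

## Elo scoring of pairwise-comparison trials

A trial list is processed in a single pass.  Before each trial the current
scores *S*₁, *S*₂ give the logistic win expectation
E₁ = 1/(1 + b^((S₂−S₁)/d)) with base b = 10 and divisor d = 400 (the
classical chess convention: a d-point gap means b:1 predicted odds), and
after it both scores move by ±k(O − E).  Defaults are k = 100 and start
score 0.  The update is applied with the winner's expectation only and the
loser receives the exact negative, so the roster sum is conserved to
machine precision at every step — the conservation tests assert 1e-9,
which pure arithmetic meets with orders of magnitude to spare.  Scores are
real-valued throughout; no integer rounding is applied.

Assumptions worth making explicit: the stimulus set is fixed (every
stimulus is initialized before the first trial, even if it first appears
late), and the measured attribute is static in time — which is precisely
why trial order is treated as noise rather than signal.  Draws are
supported as O = 0.5 for generality although a forced-choice design never
produces them; they update scores but are excluded from upset bookkeeping,
since no choice was made.

## mElo

`melo_scores` re-runs the pass over permutations of the pooled trial list
(all raters shuffled together; shuffling within rater blocks would
preserve exactly the order artifacts the average is meant to destroy) and
averages final scores per stimulus.  Sampling is with replacement from the
permutation space — immaterial for the default 100 sequences against
(trial count)! alternatives.  One master seed spawns an independent child
generator per sequence, so any subset of sequences is reproducible
regardless of evaluation order.  With `exhaustive=True` and at most 8
trials all permutations are enumerated instead, which gives the exact
permutation-average used as the oracle in the tests.

Implementation note: the multi-sequence runner keeps a (sequence ×
stimulus) score matrix and advances all sequences in lockstep over trial
positions, which turns the per-trial update into vectorized arithmetic
(100 sequences × 4,592 trials in ~0.15 s).  Its row-for-row agreement with
the literal single-sequence loop is itself a test, so the fast path never
stands unchecked.

## Consistency indices

R = 1 − Σu/N over the N decisive trials with nonzero pre-update score
difference; R′ = 1 − Σ(u·w)/Σw with w the absolute pre-update difference
summed over those same N trials.  Zero-difference trials join neither
numerator nor denominator, and N is computed per sequence (different
orderings expose different zero-difference trials).  A sequence with
N = 0 — e.g. a single trial, where scores are necessarily equal — returns
an explicit no-expectation sentinel (`R is None`) rather than 0 or 1,
and such sequences are excluded from across-sequence means with their
count reported; silently imputing either constant would bias the average.

The rater-accumulation curve re-computes the mean weighted index on the
trials of the first r raters (first-appearance order), r = 1 … R.  Its
typical shape — a rise to a plateau — indicates how many raters are needed
for stable indices; the tests assert the qualitative shape (late per-rater
changes below 0.01) rather than any particular plateau onset.

## Bradley–Terry reference fit

The MM/Zermelo fixed point π ← W/Σn/(π+π′), renormalized to the simplex
each iteration, with tol 1e-8 on the maximum relative worth change and
max_iter 10,000.  It was chosen over Newton or a GLM reformulation for its
guaranteed likelihood monotonicity and freedom from tuning.  Estimability
is checked up front: a disconnected comparison graph raises an error
naming the components, and a stimulus with no wins or no losses raises an
error suggesting the documented remedy, a pseudocount (0.5 per ordered
pair) added to every cell.  The default pseudocount is 0 so degenerate
records fail loudly.  Draws count half a win to each side.  Worths are
normalized to sum to 1 (the simplex convention), and log-worths use base
e — correlations are base-invariant, so the choice only matters for
reproducing printed values.

## Agreement statistics

The ICC follows the two-way, consistency, average-measures definition
(ICC(C,k)): from the two-way ANOVA of a complete stimuli × raters matrix,
ICC = (MS_rows − MS_error)/MS_rows, CI from F = MS_rows/MS_error with
(n−1) and (n−1)(k−1) df.  It is invariant to additive per-rater offsets,
which is the right notion when raters use the scale's anchors
differently.  Missing entries are allowed for Likert means (averaging the
raters present) but rejected for the ICC, whose ANOVA decomposition
assumes a complete layout.  Williams's t for two dependent overlapping
correlations uses the classical formula with df = n − 3 and two-sided p;
its simulated null rejection rate at α = 0.05 sits within 0.05 ± 0.01.
No multiple-testing correction is applied anywhere.

## The synthetic-data generator

What it emulates: latent strengths θ ~ Normal(0, σ_θ) on the Elo scale
(σ_θ = 200); per rater, B = 2 blocks, each a uniformly random perfect
matching (shuffle-and-pair-adjacent, whose uniformity over matchings is
asserted by test); logistic choices P(i over j) = 1/(1+10^(−(θᵢ−θⱼ)/s));
Likert responses from percepts θ + rater bias + noise cut at
equal-population thresholds into 7 levels.  Rater bias (SD 60) enters the
Likert task only: pairwise choices depend on score differences, so
additive rater offsets cancel there by construction — one of the arguments
for comparison designs.  Perceptual noise SD is 120, chosen so the
simulated Likert ICC of the full 56-rater panel lands near the very high
agreement typical of strength-rating studies (~0.99) while single raters
remain clearly noisy.  An odd roster rotates one sit-out stimulus per
block.

The choice scale defaults to s = 300.  Using the same base-10 logistic as
the Elo expectation makes s directly interpretable, and only the ratio
σ_θ/s affects choice probabilities; s = 300 was calibrated once so that
the default panel's mean unweighted consistency index falls in the
0.74–0.77 range observed in real strength-judgement panels, and left
there.  With σ_θ = 0 every choice is a fair coin flip, which is the null
panel used for the R = 0.5 calibration check.

What the generator does not emulate: response times, participant dropout,
within-rater drift or learning, lapses of attention, and any departure
from the logistic choice law.  Passing tests therefore demonstrate
correctness of the machinery and the statistical behaviour of the indices
under the stated generative model — not that any particular real panel
will reach a given R or ICC.

One consequence of the pure-logistic model with normal latents deserves
note: a draw of 82 θ's regularly contains stimuli 2.5σ from the mean that
win or lose ~98% of their trials.  For these, the Bradley–Terry log-worth
keeps stretching while Elo scores saturate (a stimulus's score stops
rising once its predicted win rate matches its observed one), so the
Pearson correlation between mElo and log-worth is typically 0.998–0.9995
on a simulated default panel, with the exact value depending on how
extreme the latent draw happens to be.  Real panels, whose effective tails
are milder, sit at the top of that range.

## Problem sizes in the test suite

Tests run the full default design (82 stimuli × 56 raters × 2 blocks =
4,592 trials) where the property concerns that design, and smaller panels
(20–40 stimuli, 12–30 raters) for structural checks; the randomized-
sequence count is reduced from 100 to 10–50 where only the mean across
sequences matters.  The replicate counts (10 panels for rater-count
monotonicity, 20 for the R′ > R property, 5,000 null replicates for the
Williams's t size) were fixed in advance of running the suite.
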