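"""Likert ratings, inter-rater ICC, and comparison with pairwise scores.

Simulates the full two-task design: every rater scores every stimulus once
on a 1-7 scale and compares all stimuli pairwise in two blocks.  Prints
the ICC of the Likert matrix, the correlation between mean Likert scores
and mElo, and the effect of halving the rater panel.
"""

from scipy.stats import spearmanr

from pairelo import (
    RandomizationPlan,
    SimConfig,
    icc_consistency_avg,
    mean_likert,
    melo_scores,
    pearson,
    rater_subset,
    simulate_panel,
)

panel = simulate_panel(SimConfig(seed=0))
likert = mean_likert(panel.ratings)
icc = icc_consistency_avg(panel.ratings)
print(
    f"Likert ICC (two-way, consistency, average measures): {icc.icc:.3f} "
    f"(95% CI {icc.ci_lower:.3f}-{icc.ci_upper:.3f})"
)

melo = melo_scores(panel.trials, plan=RandomizationPlan(seed=1)).melo
print(f"r(mean Likert, mElo) = {pearson(likert.reindex(melo.index).to_numpy(), melo):.3f}")

theta = panel.latent
for fraction, label in ((1.0, "full"), (0.5, "half"), (0.25, "quarter")):
    sub = rater_subset(panel.trials, fraction)
    m = melo_scores(sub, plan=RandomizationPlan(seed=2)).melo
    rho = spearmanr(theta.reindex(m.index), m).statistic
    print(
        f"{label:>8} panel ({len(sub.raters):2d} raters): "
        f"Spearman(latent strength, mElo) = {rho:.3f}"
    )
print(
    "\nRecovery of the true latent ordering degrades only gently as raters"
    "\nare removed - pairwise comparison panels can be small."
)
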