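"""Upset-based consistency indices R and R'.

An upset is a trial won by the member with the lower current Elo score.
R is the fraction of expectation-bearing trials without an upset; R'
weights each trial by the score gap at stake.  0.5 means random choice.
"""

from pairelo import (
    RandomizationPlan,
    SimConfig,
    mean_consistency,
    simulate_panel,
)

# a realistic panel and a pure coin-flip panel (latent_sd=0)
for label, latent_sd in (("shared perceptions", 200.0), ("coin flips", 0.0)):
    panel = simulate_panel(
        SimConfig(n_stimuli=40, n_raters=30, latent_sd=latent_sd, seed=5)
    )
    res = mean_consistency(
        panel.trials, plan=RandomizationPlan(n_sequences=50, seed=2)
    )
    print(
        f"{label:>18}: mean R = {res.mean_R:.3f}, mean R' = "
        f"{res.mean_R_weighted:.3f}  ({res.n_sequences} sequences, "
        f"{res.n_excluded} without expectations)"
    )
print(
    "\nR near 0.5 indicates random choices; R' above R means large score"
    "\ngaps are violated less often than small ones, as expected when"
    "\nraters share perceptions of the stimuli."
)
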