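"""Moderation mixed model: does habitual walking speed change the effect?

Simulates z-standardized SCL responses with a known speed effect
(beta = -0.8), a binary fast/slow walker grouping and no true interaction,
then fits the random-intercept mixed model.  The table mirrors the
parameter/beta/t/p layout used to report such models.
"""

from crowdeda.benchmark import simulate_moderation_data
from crowdeda.stats import MixedModelSpec, mixed_mediation

data = simulate_moderation_data(n_subjects=60, beta_speed=-0.8,
                                beta_moderator=0.2, beta_interaction=0.0,
                                noise_sd=0.5, seed=11)
spec = MixedModelSpec(response="z_mean_scl", condition="speed",
                      moderator="group")
fit = mixed_mediation(data, spec)
print(fit.round(4).to_string(index=False))
print("-> the speed coefficient recovers ~-0.8; the interaction term stays "
      "near zero, i.e. the grouping does not moderate the speed effect.")
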