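"""Person-level progress estimates and relative measurement precision.

EAP (posterior-mean) intercepts and slopes per student, with posterior SDs
normalized by the estimated latent-distribution SDs: the resulting relative
precision says how well a single student's initial level and progress are
resolved on the population scale.
"""

from lpgrowth import (
    GrowthModelSpec,
    SamplerConfig,
    default_growth_params,
    draw_person_effects,
    eap_estimates,
    fit_model,
    simulate_scores,
)

params = default_growth_params("student_t")
effects = draw_person_effects(params, n=400, seed=71)
data = simulate_scores(effects, params, n_timepoints=8, seed=72)

fit = fit_model(data, GrowthModelSpec(family="student_t"),
                SamplerConfig(chains=2, iterations=2000, seed=73,
                              store_person_draws=True))
est = eap_estimates(fit)
print(est.head(5).round(3).to_string(index=False))

print(f"\nmedian relative precision: initial level "
      f"{est['relprec_b0'].median():.2f}, progress {est['relprec_b1'].median():.2f}")
print("Smaller is better: a value of 0.3 means the student's posterior SD is "
      "30% of the between-student SD. Initial level is resolved much better "
      "than progress — eight timepoints pin down where a student starts far "
      "more precisely than how fast they improve.")
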