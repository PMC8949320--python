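"""Posterior predictive checking: does the fitted family reproduce the
shape of the observed score distribution?

Ten replicated datasets are drawn from the fitted model (keeping each
draw's person effects, redrawing residuals) and their five-number
summaries are compared with the observed data.
"""

from lpgrowth import (
    GrowthModelSpec,
    SamplerConfig,
    default_growth_params,
    draw_person_effects,
    fit_model,
    posterior_predictive,
    simulate_scores,
)

params = default_growth_params("student_t")
effects = draw_person_effects(params, n=400, seed=61)
data = simulate_scores(effects, params, n_timepoints=8, seed=62)

for family in ("gaussian", "student_t"):
    cfg = SamplerConfig(chains=2, iterations=1500, seed=63,
                        store_person_draws=True, person_thin=2)
    fit = fit_model(data, GrowthModelSpec(family=family), cfg)
    ppc = posterior_predictive(fit, data, n_reps=10, seed=64)
    obs = ppc["observed"]["summary"]
    reps = ppc["rep_summaries"]
    print(f"\n{family}:")
    print(f"  observed   min {obs['min']:9.1f}  q1 {obs['q1']:7.1f}  "
          f"median {obs['median']:7.1f}  q3 {obs['q3']:7.1f}  max {obs['max']:8.1f}")
    print(f"  replicated min {reps['min'].mean():9.1f}  q1 {reps['q1'].mean():7.1f}  "
          f"median {reps['median'].mean():7.1f}  q3 {reps['q3'].mean():7.1f}  "
          f"max {reps['max'].mean():8.1f}   (means over 10 reps)")

print("\nOn heavy-tailed data the Gaussian replicates miss the extreme "
      "observed minima, while the Student-t replicates cover (and typically "
      "overshoot) them — the same contrast seen in graphical checks on real "
      "reading-efficiency scores.")
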