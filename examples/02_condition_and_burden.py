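"""Compute the two individual-level covariates: body condition (residual of
the pooled log mass ~ log length regression) and tag burden (tag mass as a
percentage of body mass), then fit the binomial mixed model of individual
migration success on both.

A positive condition coefficient means heavier-for-their-length smolts
migrate more successfully; a negative burden coefficient means heavier
relative tag loads cost survival.
"""

import smoltrak as st

cfg = st.SimConfig(
    n_rivers=6, n_fish_per_river=150, years=(2019, 2020), river_distance_km=30.0,
    landscape_effects={},
    bedrock_effects={k: 3.75 for k in ("igneous", "metamorphic", "sedimentary")},
    detection_prob_first=1.0, detection_prob_last=1.0,
    duplicate_rate=0.0, out_of_window_rate=0.0, unknown_tag_rate=0.0, seed=5,
)
study = st.simulate_study(cfg)

condition = st.body_condition(study.fish)
print(f"allometry: log(mass) = {condition.intercept:.2f} + {condition.slope:.2f} log(length)")

df = study.fish.assign(
    condition=condition.residuals,
    tag_burden=st.tag_burden(study.fish),
    succeeded=study.fish["fish_id"].map(
        study.truth.fish.set_index("fish_id")["survived"]).astype(float),
)
print(f"tag burden range: {df.tag_burden.min():.2f}% .. {df.tag_burden.max():.2f}%")
print("collinearity check (VIF):", st.vif(df[["tag_burden", "condition"]]).round(3).to_dict())

fit = st.fit_individual_success(df)
print("\nbinomial GLMM (river + year random intercepts):")
print(fit.params.round(4).to_string())
print("random-effect SDs:", {k: round(v, 3) for k, v in fit.extra["sigmas"].items()})
print("\nThe generator's true slopes are +1.111 (condition) and -0.117 (burden);")
print("the fitted coefficients should recover their signs and magnitudes.")
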