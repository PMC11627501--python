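"""Repeated correlation-screening feature selection, per species.

Per repetition: hold out one of ten folds, correlate all 260 features
with age on the remaining nine-tenths, keep those with p < 0.01, fit the
linear model and record the held-out MAE.  Two reductions follow:
*common* features (selected in every repetition) and the *min-MAE* set.
"""

import xbrainage as xb

cohort, features, _, truth = xb.simulate_study(xb.SimConfig(rng_seed=7))
ages = cohort["age"]

for species in ("human", "macaque"):
    idx = cohort.index[cohort.species == species]
    sel = xb.repeated_screening(features.loc[idx], ages.loc[idx],
                                n_reps=100, n_folds=10, alpha=0.01,
                                seed=1)
    planted = set(truth.informative_features(species))
    hits = len(planted & set(sel.common_set))
    print(f"{species}: common={sel.n_common}  min-MAE={sel.n_min_mae}  "
          f"({hits}/{len(sel.common_set)} of the common set is planted "
          f"signal)")

print()
print("top-5 strongest age correlates among the 62 top-k human features:")
idx = cohort.index[cohort.species == "human"]
top62 = xb.top_k_features(features.loc[idx], ages.loc[idx], 62)
schema = xb.build_default_schema()
print(xb.top_features(features.loc[idx], ages.loc[idx], top62, schema,
                      "white_matter", n=5).round(3))
print("(signed Pearson r with age; the top-k variant supports the "
      "equal-feature-count cross-species comparison)")
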