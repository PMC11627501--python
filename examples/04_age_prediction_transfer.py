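"""Within-species age prediction and cross-species model transfer.

Within species: repeated ten-fold CV of an OLS model on z-scored
selected features.  Across species: the full-sample model is applied to
the other species' table, standardized with that species' own
statistics.  The absolute brain-age gap |actual - predicted| then shows
the transfer signature: a macaque model under-predicts human ages ever
more with age (gap-age r near +1), a human model over-predicts macaque
ages with a compressed slope (gap-age r < 0).
"""

import xbrainage as xb

cohort, features, _, _ = xb.simulate_study(xb.SimConfig(rng_seed=7))
schema = xb.build_default_schema()
ages = cohort["age"]
hum = cohort.index[cohort.species == "human"]
mac = cohort.index[cohort.species == "macaque"]
fm = xb.harmonize_by_measure(features.loc[mac], cohort.loc[mac, "site"],
                             schema, cohort.loc[mac, ["sex"]])
fh = features.loc[hum]

sel_h = xb.screen_once(fh, ages.loc[hum], 0.01)
sel_m = xb.screen_once(fm, ages.loc[mac], 0.01)

cv_h = xb.cv_predict(fh, ages.loc[hum], sel_h, n_reps=20, seed=2)
cv_m = xb.cv_predict(fm, ages.loc[mac], sel_m, n_reps=20, seed=3)
print(f"human model on humans   : R={cv_h.r:.4f}  MAE={cv_h.mae:.4f} y")
print(f"macaque model on macaques: R={cv_m.r:.4f}  MAE={cv_m.mae:.4f} y")

model_h = xb.fit_full_model(fh, ages.loc[hum], sel_h, species="human")
model_m = xb.fit_full_model(fm, ages.loc[mac], sel_m, species="macaque")
p_mh = xb.cross_predict(model_m, fh)
p_hm = xb.cross_predict(model_h, fm)
r_mh, _, mae_mh = xb.evaluate(ages.loc[hum], p_mh)
r_hm, _, mae_hm = xb.evaluate(ages.loc[mac], p_hm)
print(f"macaque model on humans : R={r_mh:.4f}  MAE={mae_mh:.4f} y")
print(f"human model on macaques : R={r_hm:.4f}  MAE={mae_hm:.4f} y")
print("(transfer is asymmetric: the macaque model, built on mostly "
      "conserved features, transfers better)")

g_h, _ = xb.gap_age_correlation(xb.brain_age_gap(ages.loc[hum], p_mh),
                                ages.loc[hum])
g_m, _ = xb.gap_age_correlation(xb.brain_age_gap(ages.loc[mac], p_hm),
                                ages.loc[mac])
print(f"gap-age correlation, human cohort : r={g_h:+.4f}")
print(f"gap-age correlation, macaque cohort: r={g_m:+.4f}")
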