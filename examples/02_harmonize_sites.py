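"""Remove macaque scanner-site effects with the empirical-Bayes adjustment.

The two macaque sites differ by planted per-feature shifts and scales.
ComBat-style harmonization removes the between-site variance while
preserving the sex covariate and the biological age signal.
"""

import pandas as pd
import xbrainage as xb

config = xb.SimConfig(rng_seed=7, site_shift_sd=0.85)
cohort, features, truth = xb.generate_cohort(config)
mac = cohort.index[cohort.species == "macaque"]
feats, site = features.loc[mac], cohort.loc[mac, "site"]


def site_r2(table):
    grand = table.mean()
    ssb = pd.Series(0.0, index=table.columns)
    for _, grp in table.groupby(site):
        ssb += len(grp) * (grp.mean() - grand) ** 2
    return ssb / ((table - grand) ** 2).sum()


schema = xb.build_default_schema()
adjusted = xb.harmonize_by_measure(feats, site, schema,
                                   covariates=cohort.loc[mac, ["sex"]])

print(f"macaque subjects per site: {site.value_counts().to_dict()}")
print(f"mean between-site variance fraction before: "
      f"{site_r2(feats).mean():.3f}")
print(f"mean between-site variance fraction after : "
      f"{site_r2(adjusted).mean():.5f}")
print("(the planted ~20% site variance collapses to ~0 while feature-age")
print(" correlations are left intact -- see the harmonization tests)")
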