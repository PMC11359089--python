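"""Contrast long- vs short-protein-lifetime subtype density changes.

The six LPL subtypes (ids 2, 3, 5, 20, 34, 35) have the slowest PSD95
turnover, the six SPL subtypes (6, 8, 11, 28, 29, 31) the fastest.  The
two-stage comparison first estimates, per region, the posterior of the
sleep-deprivation effect on the pooled density of each set, then
compares the two posterior distributions; a positive stage-2 d means
LPL subtypes changed more favourably (gained density) than SPL.
"""

import synaptome_sd as sd

catalog = sd.make_region_catalog()
lifetimes = sd.make_lifetime_table(seed=0)
cohort = sd.simulate_cohort(
    catalog, sd.CohortDesign(seed=11), sd.EffectSpec(), lifetimes)

lpl, spl = sd.lpl_spl_sets(lifetimes)
print("LPL ids:", lpl)
print("SPL ids:", spl)

contrast = sd.lpl_spl_contrast(
    cohort.subtypes, lifetimes, "ZT6SD", "ZT6", n_draws=2000, seed=11)
contrast = contrast.merge(catalog[["region_id", "area"]], on="region_id")

ctx = contrast[contrast.area == "CTX"]
print("CTX regions with stage-2 d > 0: %d / %d"
      % ((ctx.cohens_d > 0).sum(), len(ctx)))
print("BH-significant regions by area:",
      contrast[contrast.p_adj < 0.05].area.value_counts().to_dict())
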