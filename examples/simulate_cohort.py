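"""Generate a synthetic synaptome cohort and inspect its ground truth.

Builds the default 125-region catalog, the 37-subtype lifetime table and
a four-group cohort (ZT6 n=8; ZT6SD, ZT11, ZT23 n=10 each), then prints
the injected effects.  The sleep-deprived group carries a standardized
PSD95 punctum-size reduction (Cohen's d = -1) confined to cortex and
hippocampal formation, and a zero-sum subtype-density shift that favours
long-protein-lifetime subtypes.
"""

import json

import synaptome_sd as sd

catalog = sd.make_region_catalog()
lifetimes = sd.make_lifetime_table(seed=0)
cohort = sd.simulate_cohort(
    catalog, sd.CohortDesign(seed=42), sd.EffectSpec(), lifetimes)

print(f"catalog: {len(catalog)} regions "
      f"({(catalog.area == 'CTX').sum()} CTX, {(catalog.area == 'HPF').sum()} HPF)")
print(f"puncta table: {len(cohort.puncta)} rows "
      f"({cohort.puncta.animal_id.nunique()} animals x {len(catalog)} regions)")
print(f"subtype table: {len(cohort.subtypes)} rows x 37 subtype columns")
print("ground truth:", json.dumps(cohort.ground_truth, indent=1)[:400], "...")
# The multiplier below ~0.86 is what shifts the ZT6SD group's expected
# PSD95 size so that the standardized difference from ZT6 equals -1.
print("PSD95 size multiplier in affected regions:",
      round(cohort.ground_truth["psd95_size_multiplier"], 4))
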