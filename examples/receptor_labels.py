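"""Build TNBC labels from receptor calls with HER2 assay precedence.

A sample is triple-negative (y=1) when ER, PR and HER2 are all negative;
HER2 comes from FISH when a determinate FISH call exists, otherwise from
IHC status.  Samples whose HER2 assays contradict each other are flagged
as 'suspect' — their label may be wrong, making them outlier candidates.
"""

import pandas as pd

from rpod import ClinicalTable, build_tnbc_labels, flag_suspect_individuals, screen_confounders

records = [
    # sample          ER          PR          level  IHC status   FISH
    ("PT-001", "negative", "negative", "1+", "negative", "missing"),   # TNBC
    ("PT-002", "negative", "negative", "3+", "negative", "missing"),   # TNBC but suspect
    ("PT-003", "positive", "negative", "2+", "positive", "negative"),  # FISH flips HER2
    ("PT-004", "negative", "negative", "1+", "positive", "negative"),  # FISH makes it TNBC
    ("PT-005", "negative", "missing",  "0",  "negative", "missing"),   # unresolvable PR
]
clin = ClinicalTable.from_records([
    {"sample_id": s, "er_status": er, "pr_status": pr, "her2_ihc_level": lv,
     "her2_ihc_status": st, "her2_fish": fi}
    for s, er, pr, lv, st, fi in records
])

res = build_tnbc_labels(clin)
print("labels (y=1 means triple-negative):")
print(res.labels.to_string(index=False))
print("\nexcluded samples:")
print(res.excluded.to_string(index=False))
print("\nHER2 assay discordances:")
for sid, kind in flag_suspect_individuals(clin):
    print(f"  {sid}: {kind}")

# confounder screening on a larger synthetic cohort: age is associated
# with the outcome, race is not
import numpy as np

rng = np.random.default_rng(0)
y_cohort = np.repeat([0, 1], 30)
cov = pd.DataFrame({
    "age": 55 + 8 * rng.standard_normal(60) + 6 * y_cohort,
    "race": rng.choice(["a", "b", "c"], size=60),
})
print("\nunivariate confounder screen on a 60-sample cohort:")
print(screen_confounders(cov, y_cohort).to_string(index=False))
print("(continuous covariates: logistic Wald p; categorical: Fisher's exact)")
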