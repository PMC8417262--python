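"""Cohort statistics: geometry and head orientation vs brain shift.

Generates a small synthetic cohort with the built-in couplings (e.g. a
head tilt 10 degrees more downward reduces the shift by 0.18 mm) and
analyses the ground-truth fields directly: whole-brain displacement
table, per-subject gravity directions, and the Spearman/OLS correlation
grid the coupling slopes are recovered from.
"""

import pandas as pd

from pbshift.cohortstats import correlation_analysis
from pbshift.synthcohort import CohortSpec, PhantomSpec, generate_cohort

pd.set_option("display.width", 140)

cohort = generate_cohort(
    CohortSpec(n_subjects=11, seed=0),
    pspec=PhantomSpec(shape=(48, 48, 48), spacing=4.5),
    volumes=False,  # analyse truth fields; no textures or warps needed
)

print("subject geometry and pose:")
for rec in cohort[:4]:
    print(f"  {rec.id}: MCB {rec.mcb:.1f} mm, APD {rec.apd:.1f} mm, "
          f"supine gravity elevation {rec.gravity_supine.elevation:.1f} deg")
print("  ...")

df = correlation_analysis(cohort)
show = df[df.covariate.isin(["MCB", "gravity_elev_supine"])]
print("\ncorrelation grid (slopes are per 10 mm / per 10 deg):")
print(show.to_string(index=False,
                     float_format=lambda x: f"{x: .3f}"))
print("\nAt n=11 the built-in couplings appear as the strongly "
      "significant pairs; slopes approximate the generator's values "
      "(recovery is exact at larger n).")
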