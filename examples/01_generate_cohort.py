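"""Generate a synthetic cardiovascular cohort and inspect its structure.

Builds the default cohort (n=3121, four latent severity classes), derives the
carotid ultrasound summaries, and prints the per-class descriptives that the
generator is calibrated to reproduce.
"""

import pandas as pd

from endotyper import GeneratorConfig, generate_cohort
from endotyper.preprocess import cohort_summaries

config = GeneratorConfig(seed=1)
cohort = generate_cohort(config)
summaries = cohort_summaries(cohort)

print(f"cohort: {cohort.n} subjects, {len(cohort.analysis_variables())} analysis variables")
rows = []
for c in range(1, 5):
    members = cohort.true_class == c
    rows.append({
        "class": c,
        "n": int(members.sum()),
        "cimt_mean_max (mm)": summaries.loc[members, "cimt_mean_max"].mean(),
        "plaque count": cohort.data.loc[members, "plaque_count"].mean(),
        "fastest progression (mm/y)": summaries.loc[members, "fastest_prog"].mean(),
        "ASCVD %": 100 * cohort.data.loc[members, "event"].mean(),
    })
print(pd.DataFrame(rows).round(2).to_string(index=False))
print("\nEach row is one latent class: counts are exact (largest-remainder "
      "allocation); c-IMT and plaque means match the configured class "
      "targets; the overall 3-year event fraction is ~5.3%.")
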