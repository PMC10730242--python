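"""Discover atherosclerosis endotypes with the outcome-guided encoder.

Standardizes the cohort, trains the c-IMT-guided encoder, clusters its
bottleneck embedding, severity-orders the clusters, and runs the
random-outcome null control that must find nothing.
"""

import numpy as np

from endotyper import GeneratorConfig, generate_cohort, null_control, z_standardize
from endotyper.pipeline import discover_endotypes

cohort = generate_cohort(GeneratorConfig(seed=1))
discovery = discover_endotypes(cohort, seed=1)

print(f"selected k = {discovery.assignment.k} "
      f"(silhouette profile: "
      f"{ {k: round(v, 2) for k, v in discovery.selection.profile.items()} })")
for e in range(1, discovery.assignment.k + 1):
    members = discovery.assignment.labels == e
    print(f"endotype {e}: n={members.sum():4d}, "
          f"mean c-IMT_mean-max={discovery.severity[members].mean():.2f} mm")

agree = np.mean(discovery.assignment.labels == cohort.true_class)
print(f"\nagreement with planted classes: {agree:.2f} "
      "(labels are severity-ordered, endotype 1 mildest)")

Xz, _ = z_standardize(cohort, cohort.analysis_variables())
report = null_control(Xz, seed=1)
print(f"null control (random outcome): verdict = '{report.verdict}'")
print("A random outcome carries no signal, so the encoder collapses and no "
      "cluster structure should be declared — the guard that the endotypes "
      "are outcome-driven, not clustering artifacts.")
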