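"""Generate a seeded synthetic cohort and analyze it like real data.

The generator emulates the study's structure: access-dependent detection,
lognormal antral areas, an adverse subgroup with a dilated, rising antrum.
"""

from gastrus import (
    CohortConfig,
    detection_rate,
    generate_cohort,
    standard_comparisons,
    write_cohort,
)

config = CohortConfig(n_patients=41, seed=1)
patients, scans = generate_cohort(config)
paths = write_cohort(patients, scans, "scratch/simulated_cohort")

either = detection_rate(scans, "either")
print(f"wrote {paths[0]} and {paths[1]}")
print(f"{len(patients)} patients, {len(scans)} scans; antrum detected in "
      f"{either.numerator}/{either.denominator} scans ({either.pct:.1f}%)")
print()
print(standard_comparisons(patients, scans).to_string(index=False))
print()
print("Same seed, same cohort: every downstream analysis is reproducible.")
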