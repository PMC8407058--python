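# gastrus

Analytics for **gastric point-of-care ultrasound (GUS)** in emergency
abdominal surgery: quantify the gastric antrum, grade its content, stratify
aspiration / postoperative-nausea risk, and analyze whole-cohort detection
rates and postoperative antral-dilation trajectories.

Postoperative nausea and vomiting (PONV) and postoperative ileus (POI) are
frequent after emergency abdominal surgery, and the usual preventive
machinery (ERAS protocols, Apfel scoring, prophylactic nasogastric tubes) is
hard to apply in the emergency setting. Bedside ultrasound of the gastric
antrum offers a measurable alternative: the antral cross-sectional area
(CSA) tracks gastric content and volume. This package implements the full
analysis pipeline for such a cohort study — for clinical researchers who
have per-scan antral measurements (or want to simulate them) and need the
derived quantities, decision rules and statistics.

## The models

**Antral CSA** from two perpendicular diameters (anteroposterior `D1`,
craniocaudal `D2`, in mm), as the area of an ellipse:

    CSA [cm²] = (D1/10) · (D2/10) · π/4

**Predicted gastric volume** from the CSA measured in right lateral
decubitus (RLD), age-adjusted (Perlas model):

    Volume [mL] = 27.0 + 14.6 · CSA_RLD − 1.28 · age

(negative predictions are clamped to 0 mL and flagged).

**Antral grade**: G0 = no fluid in either position, G1 = fluid only in RLD,
G2 = fluid in both positions.

**Risk flowchart**: a scan is *high risk* if it shows solid (or mixed)
content, Grade-2 fluid, or predicted volume > 1.5 mL/kg; *low risk* only
when all three branches are evaluable and negative; *indeterminate*
otherwise. A patient is high risk if any postoperative scan is.

**Cohort statistics**: detection rates by position / phase / surgical
access with uncorrected Pearson chi-squared tests on 2×2 tables,
pooled-variance Student t-tests, median/IQR descriptives, and a pooled OLS
regression of the relative antral area CSA_x/CSA_0 on the postoperative day
(a slope of 1/6 per day ≈ +50 % over 72 h, the dilation signature of
adverse-outcome patients).

A seeded synthetic-cohort generator (`CohortConfig`, `generate_cohort`)
reproduces the statistical shape of the study cohort, and
`build_results_cohort()` provides a deterministic 41-patient / 94-scan
reference cohort whose marginal counts equal the published ones.

## Worked example

```python
from gastrus import Content, antral_grade, csa_from_diameters, estimate_volume

csa = csa_from_diameters(24.1, 26.1)          # 4.940 cm²
est = estimate_volume(csa, age_years=50, weight_kg=72.0)
grade = antral_grade(Content.empty, Content.empty)
print(csa, est.volume_ml, est.volume_ml_per_kg, grade.value)
```

prints `4.940 cm²`, `35.1 mL`, `0.49 mL/kg`, `G0`: an empty-pattern antrum
of median size predicts half a millilitre of gastric content per kilogram —
well below the 1.5 mL/kg threshold, so this scan is low risk.

On the reference cohort (`python examples/03_cohort_stats.py`):

```
comparison       group1 group1_rate  group1_pct        group2 group2_rate  group2_pct  statistic  p_value
  position       supine       59/94        62.8           rld       57/94        60.6   0.090038 0.764128
     phase preoperative       16/28        57.1 postoperative       46/66        69.7   1.379940 0.240111
    access laparoscopic       15/19        78.9          open        7/22        31.8   9.106757 0.002547
```

i.e. patient position and scan timing do not change antrum detection
significantly, but open surgical access does (78.9 % vs 31.8 %, p ≈ 0.003):
fresh laparotomy wounds shadow the acoustic window. Running
`examples/02_risk_flowchart.py` shows the flowchart flags only 1 of the 6
adverse-outcome patients in the 18-patient major-surgery subgroup
(prediction rate 16.7 %), while `examples/04_trajectory.py` fits the
relative-CSA regression (slope 0.167/day, ≈ +50 % over 72 h) that captures
the dilation those patients actually show.

The `gastrus` command line mirrors the same stages
(`simulate`, `assess`, `stats`, `trajectory`, `fixture`), writing CSV/JSON
outputs plus a run manifest; see `gastrus --help`.

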