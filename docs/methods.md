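# Methods

## Data model

A cohort is two CSV files joined on `patient_id`. A *patient* carries
demographics (age in years, weight in kg, BMI), surgery descriptors
(type, open/laparoscopic access, prior abdominal surgery) and a composite
adverse-outcome flag (nausea/vomiting, antiemetic therapy, delayed return of
bowel function, and/or nasogastric-tube placement). A *scan* is one bedside
examination — preoperative, or postoperative with a 1-based postoperative
day (POD) — with one measurement block per position (semi-recumbent
"supine" and right lateral decubitus, RLD). A block records whether the
antrum was detected, the qualitative content pattern
(empty/liquid/solid/mixed, `unknown` when not assessable), the two
perpendicular antral diameters (mm) and the machine-traced cross-sectional
area (cm²). Undetected positions carry no content and no measurements, by
invariant; a detected position may carry any subset of the three
measurements. Enumerations are closed lower-case vocabularies; unrecognized
values are errors, never coerced. Optional numbers are empty cells, never
sentinels, and write→read is the identity on valid records.

## Antral quantification

The "calculated" CSA treats the antrum as an ellipse:
`CSA = (D1/10)(D2/10)π/4` cm² with diameters in mm (diameters are recorded
in mm, the area in cm²; the conversion is internal and explicit). The
"measured" CSA is the traced area. Predicted gastric volume uses the
age-adjusted linear model on RLD CSA,
`V = 27.0 + 14.6·CSA_RLD − 1.28·age` mL. Two policies are fixed:

* negative raw predictions (small antrum, old age — a known property of the
  linear model) are clamped to 0 mL with a `clamped` flag, since volumes
  cannot be negative;
* supine CSA is never silently substituted for RLD CSA. When no RLD area is
  available the volume is unavailable, and downstream consumers treat that
  as missing data.

Weight normalization (`mL/kg`) requires a positive weight; the risk
threshold is 1.5 mL/kg, compared strictly (`>`), so exactly 1.5 is not high
risk.

## Grading and risk stratification

The three-grade antral system is a function of per-position fluid:
fluid-bearing contents are `liquid` and `mixed`. G0 = neither position
fluid-bearing, G1 = fluid only in RLD, G2 = fluid in both. Two genuinely
open corners were decided as follows:

* unknown supine with fluid RLD reports G1 — the minimum grade consistent
  with the observation — rather than indeterminate, so that the volume
  branch of the risk rule can still run; each such call is logged;
* fluid seen only in supine has no grade in the three-grade system and is
  reported indeterminate.

The risk flowchart evaluates, in order: (1) solid or mixed content in any
*detected* position → high; (2) Grade-2 fluid → high; (3) predicted volume
per kg above threshold → high. `mixed` content is treated as solid-bearing
(it contains solid matter), so it triggers branch 1. Low risk requires all
three branches decidable and negative: no solid in detected positions,
Grade 2 excluded (grade known, or either position known non-fluid), and a
computable volume at or below threshold. Anything else is an indeterminate
assessment — missing data is an outcome, not an error. Patient-level risk
aggregates postoperative scans (high if any scan high; indeterminate only
if all scans are); the published analysis assesses subjects without stating
an aggregation, so "any high postoperative scan" was chosen as the
clinically conservative reading. The prediction rate (sensitivity) is the
fraction of adverse-outcome patients with a determinate high assessment;
indeterminate assessments are tallied separately and excluded from the
rate.

The test suite checks the flowchart against an independently coded
brute-force truth table over every content pair × volume availability ×
weight presence combination.

## Cohort statistics

* **Detection rates** count scans (or patients, for the access comparison:
  the published access-stratified denominators, 19 + 22, equal the number
  of patients, so a patient counts as detected if any scan detects the
  antrum in the requested position).
* **2×2 chi-squared**: the uncorrected Pearson statistic
  `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` with df 1. No Yates correction — the
  uncorrected statistic reproduces all three published p-values (0.003,
  0.764, 0.240) from the published counts; the corrected one does not.
  Zero-margin tables are uninformative: statistic 0, p = 1, with a warning.
  The supine-vs-RLD comparison is on paired scans but is computed unpaired,
  matching the published analysis; a paired (McNemar-style) variant was
  considered out of scope.
* **t-test**: pooled-variance two-sample Student t (df = n₁+n₂−2),
  two-tailed; Welch available as an option but not the default, because the
  published analysis specifies the Student test.
* **Descriptives**: median and IQR with linear-interpolation quartiles (no
  convention is stated in the source; this is numpy's default), mean, and
  n−1 SD (undefined, reported absent, for a single value).

## Trajectories

Antral CSA depends strongly on individual anatomy, so the postoperative
course is analyzed on the relative scale CSA_x/CSA_0. CSA_0 is the value at
the first postoperative day *with an available value* for the requested
source and position — detection fails in about a third of scans, so a
strict POD-1 baseline would discard patients; the fallback is logged.
The baseline point (ratio exactly 1) is included by default and can be
excluded. Points are pooled across patients into a single OLS regression of
ratio on POD (one reported R² implies one pooled fit; per-patient series
remain available). RLD is the default position and "calculated" the default
source. R² is undefined (reported absent) when the ratios have zero
variance. The published R² values (≈0.70–0.73) depend on unpublished raw
data and are used only to anchor the generator's noise level, not as
targets; the fit is validated by parameter recovery against the generator's
known slope.

## Synthetic cohorts

The generator emulates the statistical shape of the study cohort, not
gastric physiology. Per patient: demographics uniform in configured ranges,
access and surgery type categorical with the cohort's mixes (19/22
laparoscopic/open, etc.), adverse outcome Bernoulli(1/3 — six of the
18-patient subgroup). Scans: one preoperative scan with probability 29/41
and Uniform{0..3} postoperative scans on consecutive PODs, matching the
printed totals of 94 scans over 41 patients (≈2.3 per patient; the stated
3–5-scan protocol is inconsistent with those totals and was not used); a
patient with no scans at all is given one postoperative scan. Detection is
Bernoulli per position given access (0.789 laparoscopic, 0.318 open, 0.66
other), with probability 0.8 (`detection_concordance`, a documented guess —
no concordance figure is published) that both positions share a single
draw; adverse patients use `adverse_detection_prob` = 1.0, because the
dilated antrum of the adverse subgroup was detectable in 6/6 of the
emulated cohort. Antral areas are lognormal (positive, right-skewed) with
target arithmetic means 4.93 cm² preoperative, 6.92 cm² postoperative, and
12.95 cm² for adverse patients' postoperative baseline; the log-scale sigma
0.35 matches the observed IQR/median ratio (≈0.45 ⇒ CV ≈ 0.34). Adverse
patients' postoperative CSA follows `base·(1 + slope·(POD−1) + ε)` with
slope 1/6 per day (+50 % over 72 h) and Gaussian ratio noise sd 0.1; other
patients have slope 0. Diameters are derived from the latent area with a
random eccentricity so the ellipse formula returns it exactly; the traced
area is the latent area times a 1.1 bias (traced areas run ~10–15 % above
calculated ones in the emulated data) with 5 % lognormal noise. Supine
areas are the RLD area with 15 % lognormal noise. All draws come from one
`numpy` generator seeded by a single integer.

What the generator does **not** model: gastric emptying kinetics,
repeated-measures correlation beyond the shared patient baseline, operator
effects, content–volume coupling (content type is drawn independently of
CSA), or informative missingness beyond the access and adverse-status
detection effects. Tests that pass on synthetic cohorts therefore validate
the pipeline's arithmetic and statistical calibration, not clinical
performance on real patients.

Separately, `build_results_cohort()` constructs a deterministic cohort by
explicit assignment whose marginal counts equal the published ones
(94 scans, 62/59/57 detections, 15/19 and 7/22 by access, grades
34/5/16/39, 6/18 adverse with exactly one flagged high). Two published
inconsistencies had to be resolved: the phase-coverage breakdown (4
pre-only + 25 both-phase patients implies 29 preoperative scans, not the
printed 28 — the scan totals win: 4 pre-only / 24 both / 13 post-only), and
the subgroup size (12 colorectal + 7 small-bowel sums to 19, not the stated
18 — the fixture uses 12 + 6). The printed per-position content marginals
are also mutually inconsistent with the printed grade counts (only 13
supine fluid-bearing scans cannot produce 16 G2 scans), so the fixture
realizes the grade and detection marginals exactly and lets content counts
follow from them.

## Numerical and testing choices

* Simulation sizes are chosen for tight calibration at modest runtime:
  type-I-error checks use 10⁴ replicates (binomial sd ≈ 0.2 % at α = 5 %),
  slope recovery 200 cohorts, subgroup power 500 replicates of 18-patient
  cohorts.
* The chi-squared asymptotic p is cross-checked against a Monte-Carlo
  permutation null (hypergeometric label shuffling, 4×10⁶ draws). Agreement
  to three decimals is an asymptotic property — the lattice discreteness
  error scales like φ(z)/sd(a) — so the check uses large well-conditioned
  tables (10⁵–4×10⁵ per arm, all expected counts ≫ 5) where the property
  genuinely holds; on small tables the exact conditional null and the
  asymptotic tail differ by design.
* The single-cohort trajectory fit has a seed-to-seed sd of ≈0.023 on a
  6-patient × 4-POD cohort, so point checks of slope recovery average ten
  seeded cohorts; the distributional check uses the median over 200.
* Hypothesis property tests run derandomized with a fixed profile.

## Limitations

The pipeline starts from measured diameters/areas — no image ingestion.
The risk flowchart is the published binary rule, not a probabilistic score.
No multiple-testing adjustment is applied (none is used in the emulated
analysis). The published per-phase median/IQR summaries and the exact R²
values are not
reproducible without the unpublished raw data and are deliberately not
treated as targets.
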