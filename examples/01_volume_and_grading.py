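"""Antral CSA, predicted gastric volume, and the antral grade for one exam.

A patient (age 50, 72 kg) is scanned in both positions; the antrum measures
24.1 x 26.1 mm in right lateral decubitus with an empty pattern in both
positions.
"""

from gastrus import Content, antral_grade, csa_from_diameters, estimate_volume

csa = csa_from_diameters(24.1, 26.1)
est = estimate_volume(csa, age_years=50, weight_kg=72.0)
grade = antral_grade(Content.empty, Content.empty)

print(f"ellipse CSA           : {csa:.3f} cm^2")
print(f"predicted volume      : {est.volume_ml:.1f} mL  ({est.volume_ml_per_kg:.2f} mL/kg)")
print(f"antral grade          : {grade.value}")
print()
print("The ellipse of the two perpendicular diameters gives the antral area;")
print("the age-adjusted linear model turns the RLD area into a gastric volume,")
print("and 0.5 mL/kg is well under the 1.5 mL/kg aspiration-risk threshold.")
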