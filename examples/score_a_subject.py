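"""Score one participant: raw measurements -> graded deficits -> FI-30.

Builds a single subject's raw clinical readings and questionnaire answers,
grades the measured items (BMI, blood pressure, random blood sugar,
GDS-15), scores the 30-item deficit vector and prints the frailty index,
its severity band and the fit/frail status.
"""

from frailkit import RawMeasurements, default_registry, score_responses
from frailkit.measurements import grade_measurements

raw = RawMeasurements(
    height_m=1.58,
    weight_kg=72,          # BMI 28.8 -> overweight, graded 0.5
    systolic=152,
    diastolic=88,          # hypertension grade 1 -> 0.33
    rbs_mmol_l=9.4,        # elevated -> 0.5
    gds_total=6,           # moderate depression -> 0.5
)

responses = {item.name: "No" for item in default_registry() if len(item.scheme.levels) == 2}
responses["self_rated_health"] = "Average"   # 0.5
responses["arthritis"] = "Yes"               # 1
responses["loneliness"] = "Yes"              # 1
responses.update({name: level.label for name, level in grade_measurements(raw).items()})

result = score_responses(responses)
print(f"deficit sum : {result.score.deficit_sum:.2f} over {30 - result.score.n_missing} items")
print(f"FI-30       : {result.score.fi:.3f}")
print(f"severity    : {result.category.value}")
print(f"binary      : {result.binary.value}")
# The FI is the fraction of measured deficits present: 4.33/30 = 0.144 here,
# which falls in the mild band (0.12 < FI <= 0.24) and is below the frailty
# cut of 0.24, so the subject counts as fit for risk modelling.
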