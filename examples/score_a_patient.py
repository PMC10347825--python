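"""Score one pregnancy with the published six-factor system.

The patient: maternal age 38 years, endometrial thickness 8 mm on
transfer day, and a day-28 scan showing a 10 mm gestational sac, 2.2 mm
yolk sac, 2.5 mm embryo with a heart rate of 88 bpm.
"""

from eplscore import PatientRecord, follow_up_recommendation, lookup_risk, published_system, score_patient

system, risk_table = published_system()
record = PatientRecord(ma=38, em=8, gsd=10, ysd=2.2, el=2.5, ehr=88)

result = score_patient(record, system)
print("Per-factor points:")
for name, pts in result.points.items():
    print(f"  {name.upper():>4}: {pts:+d}")
print(f"Total score: {result.total}  (achievable range "
      f"{system.score_min} to {system.score_max})")
print(f"Estimated risk of miscarriage: {lookup_risk(result.total, risk_table):.2f}%")
print(follow_up_recommendation(result.total))

# The total is the sum of the six category points; the risk is the
# lookup-table entry for that total. A slow heart rate (+5) and small
# sac (+2) dominate this patient's score.
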