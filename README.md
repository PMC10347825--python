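# eplscore

Integer points-based prediction of **early pregnancy loss (EPL)** —
spontaneous miscarriage at or before 12 weeks — for intrauterine
singleton pregnancies after in vitro fertilization and embryo transfer
(IVF-ET), from the first routine ultrasound scan on days 27–29 after
transfer plus simple demographics.

The package is aimed at clinical-prediction-model researchers and
reproductive-medicine data analysts. It implements the full life cycle
of a Sullivan/Framingham-style clinical score:

- **`eplscore.scoring`** — the published six-factor system (maternal
  age MA, endometrial thickness EM, gestational sac diameter GSD, yolk
  sac diameter YSD, embryonic length EL, embryonic heart rate EHR),
  patient scoring and risk lookup;
- **`eplscore.cohort`** — synthetic cohorts with the study's group
  structure (the original patient data are not public);
- **`eplscore.fit`** — logistic regression with backward stepwise
  screening and point derivation from fitted coefficients;
- **`eplscore.evaluation`** — per-cutoff sensitivity/specificity/
  PPV/NPV/accuracy tables and rank-based AUC;
- **`eplscore.pipeline` / `eplscore` CLI** — the derivation pipeline
  end to end.

## The model

Each factor *i* has a per-unit log-odds coefficient βᵢ from a binary
logistic regression of EPL, and clinical categories *j* with
representative values *W*ᵢⱼ; one category per factor is the reference
with value *W*ᵢREF. Integer points are

    Points_ij = round( βᵢ (W_ij − W_iREF) / B ),      B = 5 β_MA = 0.46

with half-away-from-zero rounding, so five years of maternal age cost
one point. YSD risk is U-shaped — both small and large yolk sacs are
abnormal — so its deviations are scored in absolute value. A patient's
total (achievable range **−8 to 14**) indexes a lookup table of
estimated miscarriage risk; a total of **5 points (30.03% risk)** is the
recommended triage cutoff: at or above it, repeat the scan in 7–10
days; below it, the next routine scan is day 45 after transfer.

## Worked example

```python
from eplscore import PatientRecord, lookup_risk, published_system, score_patient

system, risk_table = published_system()
patient = PatientRecord(ma=38, em=8, gsd=10, ysd=2.2, el=2.5, ehr=88)
result = score_patient(patient, system)
print(result.total, dict(result.points))
print(lookup_risk(result.total, risk_table))
```

prints

```
9 {'ma': 0, 'gsd': 2, 'el': 0, 'ehr': 5, 'ysd': 1, 'em': 1}
70.67
```

— a 38-year-old with a thin endometrium (8 mm, +1), small sac (10 mm,
+2), small yolk sac (2.2 mm, +1) and a slow embryonic heart rate
(88 bpm, +5) totals 9 points, an estimated 70.67% risk of miscarriage;
the scan should be repeated in 7–10 days before any intervention. The
same calculation from a shell:

```bash
eplscore score --ma 38 --em 8 --gsd 10 --ysd 2.2 --el 2.5 --ehr 88
```

The `examples/` directory holds one short script per capability
(scoring, simulation, derivation, evaluation, full pipeline); each
prints its results with a note on what they mean.

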