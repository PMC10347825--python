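{
  "description": "Published six-factor early-pregnancy-loss points system (first routine scan, days 27-29 after embryo transfer) with its risk lookup table. Interval bounds are half-open [lower, upper); the upper cut of the middle gestational-sac and embryonic-length categories sits half a measurement resolution (0.05 mm) above the printed bound so that a value recorded exactly at the printed bound falls in the middle category.",
  "B": 0.46,
  "factors": [
    {
      "name": "ma",
      "units": "years",
      "beta": 0.092,
      "deviation_mode": "signed",
      "categories": [
        {"label": "<30", "lower": null, "upper": 30.0, "representative_value": 26.0, "is_base": false, "points": -2},
        {"label": "30-39", "lower": 30.0, "upper": 40.0, "representative_value": 34.5, "is_base": true, "points": 0},
        {"label": ">=40", "lower": 40.0, "upper": null, "representative_value": 42.0, "is_base": false, "points": 2}
      ]
    },
    {
      "name": "gsd",
      "units": "mm",
      "beta": -0.115,
      "deviation_mode": "signed",
      "categories": [
        {"label": "<9.0", "lower": null, "upper": 9.0, "representative_value": 6.2, "is_base": false, "points": 3},
        {"label": "9.0-12.9", "lower": 9.0, "upper": 13.0, "representative_value": 11.0, "is_base": false, "points": 2},
        {"label": "13.0-27.0", "lower": 13.0, "upper": 27.05, "representative_value": 19.0, "is_base": true, "points": 0},
        {"label": ">27.0", "lower": 27.05, "upper": null, "representative_value": 27.3, "is_base": false, "points": -2}
      ]
    },
    {
      "name": "el",
      "units": "mm",
      "beta": -0.245,
      "deviation_mode": "signed",
      "categories": [
        {"label": "<2.0", "lower": null, "upper": 2.0, "representative_value": 1.0, "is_base": false, "points": 2},
        {"label": "2.1-6.3", "lower": 2.0, "upper": 6.35, "representative_value": 4.2, "is_base": true, "points": 0},
        {"label": ">6.3", "lower": 6.35, "upper": null, "representative_value": 6.5, "is_base": false, "points": -1}
      ]
    },
    {
      "name": "ehr",
      "units": "bpm",
      "beta": -0.034,
      "deviation_mode": "signed",
      "categories": [
        {"label": "<100", "lower": null, "upper": 100.0, "representative_value": 50.0, "is_base": false, "points": 5},
        {"label": "100-130", "lower": 100.0, "upper": 130.0, "representative_value": 115.0, "is_base": true, "points": 0},
        {"label": ">=130", "lower": 130.0, "upper": null, "representative_value": 140.0, "is_base": false, "points": -2}
      ]
    },
    {
      "name": "ysd",
      "units": "mm",
      "beta": -0.159,
      "deviation_mode": "absolute",
      "categories": [
        {"label": "<3.00", "lower": null, "upper": 3.0, "representative_value": 1.5, "is_base": false, "points": 1},
        {"label": "3.00-4.99", "lower": 3.0, "upper": 5.0, "representative_value": 4.0, "is_base": true, "points": 0},
        {"label": ">=5.00", "lower": 5.0, "upper": null, "representative_value": 6.0, "is_base": false, "points": 1}
      ]
    },
    {
      "name": "em",
      "units": "mm",
      "beta": -0.074,
      "deviation_mode": "signed",
      "categories": [
        {"label": "<10.0", "lower": null, "upper": 10.0, "representative_value": 5.0, "is_base": false, "points": 1},
        {"label": "10-14.99", "lower": 10.0, "upper": 15.0, "representative_value": 12.5, "is_base": true, "points": 0},
        {"label": ">=15.00", "lower": 15.0, "upper": null, "representative_value": 16.3, "is_base": false, "points": -1}
      ]
    }
  ],
  "risk_table": [
    {"total": -8, "estimated_risk": 0.18},
    {"total": -7, "estimated_risk": 0.24},
    {"total": -6, "estimated_risk": 0.31},
    {"total": -5, "estimated_risk": 0.54},
    {"total": -4, "estimated_risk": 0.81},
    {"total": -3, "estimated_risk": 1.24},
    {"total": -2, "estimated_risk": 1.85},
    {"total": -1, "estimated_risk": 2.84},
    {"total": 0, "estimated_risk": 4.2},
    {"total": 1, "estimated_risk": 7.33},
    {"total": 2, "estimated_risk": 11.02},
    {"total": 3, "estimated_risk": 15.57},
    {"total": 4, "estimated_risk": 22.03},
    {"total": 5, "estimated_risk": 30.03},
    {"total": 6, "estimated_risk": 39.55},
    {"total": 7, "estimated_risk": 50.59},
    {"total": 8, "estimated_risk": 60.5},
    {"total": 9, "estimated_risk": 70.67},
    {"total": 10, "estimated_risk": 78.54},
    {"total": 11, "estimated_risk": 84.9},
    {"total": 12, "estimated_risk": 89.51},
    {"total": 13, "estimated_risk": 92.65},
    {"total": 14, "estimated_risk": 95.42}
  ]
}
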