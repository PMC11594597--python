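# Default 5-year CVD risk-management cost schedule (NZD), version 1.
# Consultation/diagnostic unit costs and funded medication daily costs with
# min/mid/max tiers; assessment frequencies per risk category over 5 years.
version: 1
currency: NZD
consultation:
  gp_visit: {min: 80.00, mid: 80.00, max: 80.00}
  nurse_visit: {min: 40.00, mid: 40.00, max: 40.00}
  lipid_profile: {min: 11.64, mid: 22.89, max: 46.50}
  blood_glucose: {min: 15.12, mid: 24.27, max: 39.50}
  ecg: {min: 60.00, mid: 68.80, max: 85.00}
assessments_per_5y:
  low: 2
  moderate: 3
  high: 5
medication_daily:
  statin: {min: 0.05, mid: 0.05, max: 0.05}
  antihypertensive: {min: 0.03, mid: 0.25, max: 2.03}
  antithrombotic: {min: 0.01, mid: 0.14, max: 0.36}
medication_bundle:
  low: []
  moderate: [statin, antihypertensive]
  high: [statin, antihypertensive, antithrombotic]
inpatient_event_cost:
  min: 1200.00
  max: 5500.00
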