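{
  "name": "Nursing Score (home palliative care)",
  "categories": [
    {"id": "parenteral_access", "label": "Parenteral access", "points": "5"},
    {"id": "tubes", "label": "Tubes", "points": "1"},
    {"id": "simple_wound_care", "label": "Simple wound care", "points": "1"},
    {"id": "complex_wound_care", "label": "Complex wound care", "points": "2.5"},
    {"id": "hygiene", "label": "Hygiene", "points": "2"},
    {"id": "delirium", "label": "Delirium", "points": "2.5"},
    {"id": "social_family_issues", "label": "Social/family issues", "points": "2"}
  ],
  "problems": [
    {"id": "subcutaneous_hydration", "label": "Subcutaneous for hydration", "category_id": "parenteral_access"},
    {"id": "parenteral_medication", "label": "Parenteral medication (EV, IM, SC)", "category_id": "parenteral_access"},
    {"id": "palliative_sedation", "label": "Palliative sedation therapy", "category_id": "parenteral_access"},
    {"id": "urinary_catheter", "label": "Urinary catheter", "category_id": "tubes"},
    {"id": "nasogastric_tube", "label": "Nasogastric tube", "category_id": "tubes"},
    {"id": "gastrostomy", "label": "Gastrostomy", "category_id": "tubes"},
    {"id": "grade1_pressure_ulcer", "label": "Grade I pressure ulcers", "category_id": "simple_wound_care"},
    {"id": "grade2_pressure_ulcer", "label": "Grade II pressure ulcers", "category_id": "simple_wound_care"},
    {"id": "enterocutaneous_fistula", "label": "Enterocutaneous fistula", "category_id": "complex_wound_care"},
    {"id": "other_fistula", "label": "Other fistulas", "category_id": "complex_wound_care"},
    {"id": "tracheostomy", "label": "Tracheostomy", "category_id": "complex_wound_care"},
    {"id": "colostomy", "label": "Colostomy", "category_id": "complex_wound_care"},
    {"id": "grade3_pressure_ulcer", "label": "Grade III pressure ulcers", "category_id": "complex_wound_care"},
    {"id": "grade4_pressure_ulcer", "label": "Grade IV pressure ulcers", "category_id": "complex_wound_care"},
    {"id": "hygiene_comfort", "label": "Hygiene and comfort", "category_id": "hygiene"},
    {"id": "delirium", "label": "Delirium", "category_id": "delirium"},
    {"id": "opioid_initiation", "label": "Initiation of opioid therapy (training required)", "category_id": "social_family_issues"},
    {"id": "high_risk_medication", "label": "Initiation of high-risk medication (anticoagulation, insulin, others)", "category_id": "social_family_issues"},
    {"id": "prolonged_hospitalisation_discharge", "label": "Discharge after prolonged hospitalization (>=15 days)", "category_id": "social_family_issues"},
    {"id": "ineffective_family_caregivers", "label": "Ineffective family caregivers", "category_id": "social_family_issues"},
    {"id": "patient_psychiatric_disorder", "label": "Patient with psychiatric disorder", "category_id": "social_family_issues"},
    {"id": "caregiver_psychiatric_disorder", "label": "Primary caregiver with psychiatric disorder", "category_id": "social_family_issues"}
  ]
}
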