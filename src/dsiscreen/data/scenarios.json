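[
  {"name": "demographic_cardiovascular", "block": "base_demographic_cardiovascular",
   "include": ["Demographic", "Cardiovascular"]},
  {"name": "demographic_cardiovascular_plus_cognition", "block": "base_demographic_cardiovascular",
   "include": ["Demographic", "Cardiovascular", "Cognition"]},
  {"name": "demographic_cardiovascular_plus_apoe", "block": "base_demographic_cardiovascular",
   "include": ["Demographic", "Cardiovascular", "APOE"]},
  {"name": "demographic_cardiovascular_plus_mta", "block": "base_demographic_cardiovascular",
   "include": ["Demographic", "Cardiovascular", "MRI/VisualMTA"]},
  {"name": "demographic_cardiovascular_plus_mri", "block": "base_demographic_cardiovascular",
   "include": ["Demographic", "Cardiovascular", "MRI"]},
  {"name": "demo_cardio_cognition_plus_apoe", "block": "base_with_cognition",
   "include": ["Demographic", "Cardiovascular", "Cognition", "APOE"]},
  {"name": "demo_cardio_cognition_plus_mta", "block": "base_with_cognition",
   "include": ["Demographic", "Cardiovascular", "Cognition", "MRI/VisualMTA"]},
  {"name": "demo_cardio_cognition_plus_mri", "block": "base_with_cognition",
   "include": ["Demographic", "Cardiovascular", "Cognition", "MRI"]},
  {"name": "all_except_mri_plus_mta", "block": "base_without_mri",
   "include": ["Demographic", "Cardiovascular", "Cognition", "APOE", "MRI/VisualMTA"]},
  {"name": "complete_model", "block": "base_without_mri",
   "include": null},
  {"name": "apoe_only", "block": "apoe_mri_combination",
   "include": ["APOE"]},
  {"name": "apoe_plus_mta", "block": "apoe_mri_combination",
   "include": ["APOE", "MRI/VisualMTA"]},
  {"name": "apoe_plus_mri", "block": "apoe_mri_combination",
   "include": ["APOE", "MRI"]},
  {"name": "mri_all_modalities", "block": "mri_leave_one_out",
   "include": ["MRI"]},
  {"name": "mri_without_volumes", "block": "mri_leave_one_out",
   "include": ["MRI"], "exclude": ["MRI/Volumes"]},
  {"name": "mri_without_mta", "block": "mri_leave_one_out",
   "include": ["MRI"], "exclude": ["MRI/VisualMTA"]},
  {"name": "mri_without_thickness", "block": "mri_leave_one_out",
   "include": ["MRI"], "exclude": ["MRI/ADSignatureThickness"]},
  {"name": "apoe_mri_without_volumes", "block": "apoe_mri_leave_one_out",
   "include": ["APOE", "MRI"], "exclude": ["MRI/Volumes"]},
  {"name": "apoe_mri_without_mta", "block": "apoe_mri_leave_one_out",
   "include": ["APOE", "MRI"], "exclude": ["MRI/VisualMTA"]},
  {"name": "apoe_mri_without_thickness", "block": "apoe_mri_leave_one_out",
   "include": ["APOE", "MRI"], "exclude": ["MRI/ADSignatureThickness"]}
]
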