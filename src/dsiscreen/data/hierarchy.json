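{
  "name": "DSI",
  "children": [
    {
      "name": "Demographic",
      "features": ["sex_female", "age", "education_years"]
    },
    {
      "name": "Cardiovascular",
      "features": ["bmi", "hypertension"]
    },
    {
      "name": "APOE",
      "features": ["apoe_e4_carrier"]
    },
    {
      "name": "Cognition",
      "features": ["ntb_total", "ntb_memory", "ntb_speed", "ntb_executive"]
    },
    {
      "name": "MRI",
      "children": [
        {
          "name": "Volumes",
          "features": [
            "vol_total_cortex",
            "vol_total_gray_matter",
            "vol_cerebellum_cortex",
            "vol_thalamus_proper",
            "vol_caudate",
            "vol_putamen",
            "vol_pallidum",
            "vol_brain_stem",
            "vol_hippocampus",
            "vol_amygdala",
            "vol_accumbens_area",
            "vol_ventral_diencephalon",
            "vol_csf",
            "vol_optic_chiasm",
            "vol_corpus_callosum"
          ]
        },
        {
          "name": "VisualMTA",
          "features": ["mta_rating"]
        },
        {
          "name": "ADSignatureThickness",
          "features": ["ad_signature_thickness"]
        }
      ]
    }
  ]
}
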