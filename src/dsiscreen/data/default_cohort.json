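{
  "n_negative": 28,
  "n_positive": 20,
  "seed": 0,
  "copula_correlation": null,
  "features": [
    {"name": "sex_female", "kind": "binary", "group": "Demographic",
     "neg_params": {"p": 0.5}, "pos_params": {"p": 0.4},
     "direction_truth": "lower_in_positive"},
    {"name": "age", "kind": "continuous", "group": "Demographic",
     "neg_params": {"mean": 70.2, "sd": 5.8}, "pos_params": {"mean": 71.6, "sd": 3.5},
     "direction_truth": "higher_in_positive"},
    {"name": "education_years", "kind": "continuous", "group": "Demographic",
     "neg_params": {"mean": 9.7, "sd": 2.9}, "pos_params": {"mean": 8.9, "sd": 2.0},
     "direction_truth": "lower_in_positive"},
    {"name": "bmi", "kind": "continuous", "group": "Cardiovascular",
     "neg_params": {"mean": 27.9, "sd": 3.6}, "pos_params": {"mean": 26.2, "sd": 2.6},
     "direction_truth": "lower_in_positive"},
    {"name": "hypertension", "kind": "binary", "group": "Cardiovascular",
     "neg_params": {"p": 0.35714285714285715}, "pos_params": {"p": 0.45},
     "direction_truth": "higher_in_positive"},
    {"name": "apoe_e4_carrier", "kind": "binary", "group": "APOE",
     "neg_params": {"p": 0.14285714285714285}, "pos_params": {"p": 0.5263157894736842},
     "missing_rate_neg": 0.0, "missing_rate_pos": 0.05,
     "direction_truth": "higher_in_positive"},
    {"name": "ntb_total", "kind": "continuous", "group": "Cognition",
     "neg_params": {"mean": 0.04, "sd": 0.53}, "pos_params": {"mean": -0.09, "sd": 0.5},
     "direction_truth": "lower_in_positive"},
    {"name": "ntb_memory", "kind": "continuous", "group": "Cognition",
     "neg_params": {"mean": -0.11, "sd": 0.52}, "pos_params": {"mean": 0.04, "sd": 0.64},
     "direction_truth": "higher_in_positive"},
    {"name": "ntb_speed", "kind": "continuous", "group": "Cognition",
     "neg_params": {"mean": 0.16, "sd": 0.95}, "pos_params": {"mean": -0.1, "sd": 0.77},
     "direction_truth": "lower_in_positive"},
    {"name": "ntb_executive", "kind": "continuous", "group": "Cognition",
     "neg_params": {"mean": 0.16, "sd": 0.58}, "pos_params": {"mean": -0.22, "sd": 0.44},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_total_cortex", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.29, "sd": 0.03}, "pos_params": {"mean": 0.27, "sd": 0.03},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_total_gray_matter", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.39, "sd": 0.05}, "pos_params": {"mean": 0.36, "sd": 0.04},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_cerebellum_cortex", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.063, "sd": 0.009}, "pos_params": {"mean": 0.059, "sd": 0.008},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_thalamus_proper", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.0093, "sd": 0.0012}, "pos_params": {"mean": 0.0084, "sd": 0.0011},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_caudate", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.0049, "sd": 0.00086}, "pos_params": {"mean": 0.0045, "sd": 0.00077},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_putamen", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.007, "sd": 0.0013}, "pos_params": {"mean": 0.0061, "sd": 0.001},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_pallidum", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.0019, "sd": 0.00035}, "pos_params": {"mean": 0.0018, "sd": 0.00029},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_brain_stem", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.014, "sd": 0.002}, "pos_params": {"mean": 0.014, "sd": 0.002},
     "direction_truth": "none"},
    {"name": "vol_hippocampus", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.0052, "sd": 0.00097}, "pos_params": {"mean": 0.0046, "sd": 0.00081},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_amygdala", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.0023, "sd": 0.00046}, "pos_params": {"mean": 0.002, "sd": 0.0003},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_accumbens_area", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.00066, "sd": 0.00013}, "pos_params": {"mean": 0.00056, "sd": 0.00013},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_ventral_diencephalon", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.005, "sd": 0.00057}, "pos_params": {"mean": 0.0047, "sd": 0.00041},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_csf", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.00088, "sd": 0.00014}, "pos_params": {"mean": 0.00081, "sd": 0.00014},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_optic_chiasm", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.00014, "sd": 3.6e-05}, "pos_params": {"mean": 0.00012, "sd": 4.6e-05},
     "direction_truth": "lower_in_positive"},
    {"name": "vol_corpus_callosum", "kind": "continuous", "group": "Volumes",
     "neg_params": {"mean": 0.002, "sd": 0.00043}, "pos_params": {"mean": 0.0017, "sd": 0.00038},
     "direction_truth": "lower_in_positive"},
    {"name": "mta_rating", "kind": "ordinal", "group": "VisualMTA",
     "neg_params": {"mean": 1.0, "sd": 0.7}, "pos_params": {"mean": 1.6, "sd": 0.7},
     "direction_truth": "higher_in_positive"},
    {"name": "ad_signature_thickness", "kind": "continuous", "group": "ADSignatureThickness",
     "neg_params": {"mean": 2.8, "sd": 0.1}, "pos_params": {"mean": 2.7, "sd": 0.1},
     "direction_truth": "lower_in_positive"}
  ]
}
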