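{
  "simulate": true,
  "design": {
    "treatments": [
      "CK",
      "T1",
      "T10"
    ],
    "control": "CK",
    "seeds_per_dish": 30,
    "dishes_per_treatment": 4,
    "physio_bio_reps": 4,
    "physio_tech_reps": 3,
    "rng_seed": 0
  },
  "germination_effects": {
    "CK": {
      "p_germ_day7": 0.8,
      "p_germ_day3_given_day7": 0.7,
      "mean_radicle_mm": 12.0,
      "mean_germ_mm": 8.0,
      "mean_height_cm": 2.8,
      "cv_morpho": 0.25,
      "physio_multipliers": {},
      "physio_cv": 0.1
    },
    "T1": {
      "p_germ_day7": 0.96,
      "p_germ_day3_given_day7": 0.875,
      "mean_radicle_mm": 16.200000000000003,
      "mean_germ_mm": 10.8,
      "mean_height_cm": 3.78,
      "cv_morpho": 0.25,
      "physio_multipliers": {},
      "physio_cv": 0.1
    },
    "T10": {
      "p_germ_day7": 0.8400000000000001,
      "p_germ_day3_given_day7": 0.7,
      "mean_radicle_mm": 12.72,
      "mean_germ_mm": 8.48,
      "mean_height_cm": 2.968,
      "cv_morpho": 0.25,
      "physio_multipliers": {},
      "physio_cv": 0.1
    }
  },
  "physiology_effects": {
    "CK": {
      "p_germ_day7": 0.8,
      "p_germ_day3_given_day7": 0.7,
      "mean_radicle_mm": 12.0,
      "mean_germ_mm": 8.0,
      "mean_height_cm": 2.8,
      "cv_morpho": 0.25,
      "physio_multipliers": {},
      "physio_cv": 0.1
    },
    "T1": {
      "p_germ_day7": 0.8,
      "p_germ_day3_given_day7": 0.7,
      "mean_radicle_mm": 12.0,
      "mean_germ_mm": 8.0,
      "mean_height_cm": 2.8,
      "cv_morpho": 0.25,
      "physio_multipliers": {
        "O2_minus": 1.3,
        "MDA": 0.5,
        "ASA": 1.59,
        "DHA": 4.55,
        "GR": 4.15,
        "Pro": 1.28
      },
      "physio_cv": 0.1
    },
    "T10": {
      "p_germ_day7": 0.8,
      "p_germ_day3_given_day7": 0.7,
      "mean_radicle_mm": 12.0,
      "mean_germ_mm": 8.0,
      "mean_height_cm": 2.8,
      "cv_morpho": 0.25,
      "physio_multipliers": {
        "CAT": 1.79,
        "GR": 4.95,
        "DHA": 1.59,
        "SS": 1.46,
        "Pro": 1.55
      },
      "physio_cv": 0.1
    }
  },
  "control_means": null,
  "germination_csv": null,
  "seedlings_csv": null,
  "physiology_csv": null,
  "alpha": 0.05,
  "se_parameters": [
    "germination_percentage",
    "germination_potential",
    "radicle_mm",
    "germ_mm",
    "height_cm",
    "svi"
  ],
  "ri_basis": "treatment_means",
  "topsis_normalization": "vector",
  "benefit_flags": null,
  "importance_n_estimators": 500,
  "importance_n_rounds": 50,
  "rng_seed": 0
}
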