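{
  "simulate": true,
  "design": {
    "treatments": [
      "CK",
      "T1",
      "T2",
      "T3",
      "T4",
      "T5",
      "T6",
      "T7",
      "T8",
      "T9",
      "T10"
    ],
    "control": "CK",
    "seeds_per_dish": 30,
    "dishes_per_treatment": 4,
    "physio_bio_reps": 4,
    "physio_tech_reps": 3,
    "rng_seed": 0
  },
  "germination_effects": null,
  "physiology_effects": null,
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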