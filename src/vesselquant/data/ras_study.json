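{
  "name": "ras_study",
  "description": "Synthetic RAS-/RAS+ trunk vasculature study, n=20 larvae per group",
  "master_seed": 20,
  "groups": {
    "ras_minus": {
      "phenotype": "ras-minus",
      "n": 20
    },
    "ras_plus": {
      "phenotype": "ras-plus",
      "n": 20
    }
  },
  "acquisition": {
    "dt_ms": 160.0,
    "n_repeats": 4,
    "n_depth": 8,
    "vessel_z_band": [
      3,
      6
    ],
    "tissue_intensity": 0.5,
    "bulk_amplitude_rad": 0.5,
    "phase_noise_sigma": 0.15,
    "amplitude_noise_sigma": 0.03
  },
  "reconstruction": {
    "pair_separation": 1,
    "mask_threshold": 0.2,
    "aggregation": "mean_abs",
    "median_radius_px": 3,
    "directional_filter": false,
    "threshold": "auto",
    "background_roi": [
      0,
      10,
      0,
      300
    ]
  },
  "metrics": {
    "roi": [
      12,
      148,
      8,
      292
    ]
  },
  "gfp_blur_px": 1.0,
  "gfp_noise_sigma": 0.05
}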