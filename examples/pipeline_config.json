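{
  "seed": 7,
  "outdir": "pipeline_demo",
  "stages": ["simulate", "quantify", "calibrate", "fit", "electro", "mixing"],
  "simulate": {
    "n_pg_levels": [0.0, 0.1, 0.25, 0.375, 0.5],
    "k_b0": 4.7,
    "b_decay": 3.2,
    "dna_max_true": 0.4,
    "cv_vesicle": 0.3,
    "ionic_strength_mM": 150.0,
    "dna_added_levels": [0.05, 0.1, 0.2, 0.5, 1.0, 2.0],
    "n_vesicles_per_level": 100,
    "intensity_noise_sd": 5.0,
    "render_images": true,
    "n_render": 2
  },
  "calibrate": {},
  "fit": {"n_bootstrap": 100},
  "electro": {"n_bootstrap": 100},
  "mixing": {"n_vesicles": 500, "onchip_n_vesicles": 150}
}
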