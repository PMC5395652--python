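{
  "input_params": {
    "n1": 10,
    "a1": 540.0,
    "ktr1": 0.00015,
    "n2": 4,
    "a2": 160.0,
    "ktr2": 0.00018,
    "r1": 0.024,
    "r2": 0.004,
    "k1": 0.00764,
    "k2": 0.000476
  },
  "pk_params": {
    "k_el": 0.013,
    "k_pt": 0.0685,
    "k_tp": 0.0846,
    "v_c_ml_per_kg": 111.0,
    "k_on": 0.000411,
    "k_off": 0.566,
    "k_int": 0.00342,
    "r_tot": 1240.0
  },
  "schedule": {
    "label": "sparse",
    "timescale": "long",
    "times_min": [
      2880.0,
      10080.0,
      20160.0,
      30240.0,
      40320.0,
      50400.0,
      60480.0,
      70560.0,
      80640.0,
      90720.0,
      100800.0,
      110880.0,
      120960.0
    ]
  },
  "noise": {
    "family": "student_t",
    "sigma": 0.1,
    "df": 4.0
  },
  "seed": 101,
  "n_redraws": 0,
  "description": "synthetic mock dose-group dataset (2 mg); not real clinical data",
  "dose_mg": 2.0
}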