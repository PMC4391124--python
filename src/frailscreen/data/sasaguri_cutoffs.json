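{
  "source": "Sasaguri Genkimon Study baseline cohort (n = 1527), published operational definition of the frailty phenotype",
  "version": 1,
  "grip_kg": {
    "male": {"bmi_lt_18.5": 25.0, "bmi_18.5_25": 30.0, "bmi_25_30": 31.5, "bmi_ge_30": 33.0},
    "female": {"bmi_lt_18.5": 17.5, "bmi_18.5_25": 19.5, "bmi_25_30": 20.5, "bmi_ge_30": 19.75}
  },
  "gait_time_s": {
    "male": {"short": 3.56, "tall": 3.21},
    "female": {"short": 4.25, "tall": 3.61}
  },
  "height_median_cm": {"male": 162.0, "female": 148.7},
  "aee_kcal_kg_day": {"male": 6.2, "female": 7.13}
}
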