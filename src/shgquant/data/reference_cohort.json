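{
  "description": "Published per-group summary statistics (mean, SD, range, N) of tumor-stroma-interface and tumor-bulk F/B and FAV, and clinical covariates, for a colon adenocarcinoma (CRC) and an invasive ductal carcinoma (IDC) cohort split into two demographic groups (WCA, BAA). Used for internal-consistency checks of pooled-mean aggregation and printed-count statistics.",
  "CRC": {
    "groups": {
      "WCA": {
        "n": 77,
        "metrics": {
          "FB_TSI": {"mean": 16.08, "sd": 4.36, "min": 8.13, "max": 26.66, "n_observed": 77},
          "FB_TB": {"mean": 7.01, "sd": 3.33, "min": 2.57, "max": 20.62, "n_observed": 77},
          "FAV_TSI": {"mean": 39.18, "sd": 7.46, "min": 22.56, "max": 61.66, "n_observed": 77},
          "FAV_TB": {"mean": 44.42, "sd": 7.83, "min": 27.79, "max": 61.95, "n_observed": 77}
        },
        "bmi": {"mean": 28.52, "sd": 4.95, "n_observed": 67},
        "age": {"mean": 67.79, "sd": 13.03, "n_observed": 77},
        "pt_stage": {"T1": 53, "T2": 24, "T3": 0},
        "grade": {"1": 16, "2": 46, "3": 15},
        "smoking": {"yes": 36, "no": 41},
        "sex": {"F": 38, "M": 39}
      },
      "BAA": {
        "n": 11,
        "metrics": {
          "FB_TSI": {"mean": 18.69, "sd": 3.74, "min": 13.51, "max": 24.36, "n_observed": 11},
          "FB_TB": {"mean": 8.31, "sd": 2.55, "min": 3.80, "max": 13.17, "n_observed": 11},
          "FAV_TSI": {"mean": 40.49, "sd": 7.25, "min": 27.52, "max": 50.93, "n_observed": 11},
          "FAV_TB": {"mean": 43.95, "sd": 10.29, "min": 27.05, "max": 64.25, "n_observed": 11}
        },
        "bmi": {"mean": 30.94, "sd": 6.52, "n_observed": 9},
        "age": {"mean": 62.64, "sd": 8.59, "n_observed": 11},
        "pt_stage": {"T1": 8, "T2": 3, "T3": 0},
        "grade": {"1": 1, "2": 9, "3": 1},
        "smoking": {"yes": 4, "no": 7},
        "sex": {"F": 4, "M": 7}
      }
    }
  },
  "IDC": {
    "groups": {
      "WCA": {
        "n": 223,
        "metrics": {
          "FB_TSI": {"mean": 15.36, "sd": 5.71, "min": 2.40, "max": 29.77, "n_observed": 223},
          "FB_TB": {"mean": 10.57, "sd": 4.83, "min": 1.33, "max": 29.75, "n_observed": 223},
          "FAV_TSI": {"mean": 46.03, "sd": 9.16, "min": 24.60, "max": 74.10, "n_observed": 223},
          "FAV_TB": {"mean": 47.23, "sd": 7.63, "min": 19.54, "max": 69.14, "n_observed": 223}
        },
        "bmi": {"mean": 27.57, "sd": 5.88, "n_observed": 83},
        "age": {"mean": 59.41, "sd": 12.96, "n_observed": 222},
        "pt_stage": {"T1": 159, "T2": 51, "T3": 6},
        "grade": {"1": 91, "2": 86, "3": 31},
        "smoking": {"yes": 83, "no": 93},
        "sex": {"F": 223, "M": 0}
      },
      "BAA": {
        "n": 20,
        "metrics": {
          "FB_TSI": {"mean": 12.39, "sd": 5.59, "min": 4.70, "max": 23.94, "n_observed": 20},
          "FB_TB": {"mean": 10.20, "sd": 5.57, "min": 1.27, "max": 20.94, "n_observed": 20},
          "FAV_TSI": {"mean": 46.76, "sd": 9.10, "min": 28.19, "max": 63.81, "n_observed": 20},
          "FAV_TB": {"mean": 45.92, "sd": 8.31, "min": 30.93, "max": 60.65, "n_observed": 20}
        },
        "bmi": {"mean": 34.59, "sd": 6.69, "n_observed": 8},
        "age": {"mean": 56.10, "sd": 11.25, "n_observed": 20},
        "pt_stage": {"T1": 15, "T2": 5, "T3": 0},
        "grade": {"1": 12, "2": 7, "3": 1},
        "smoking": {"yes": 11, "no": 6},
        "sex": {"F": 20, "M": 0}
      }
    }
  }
}
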