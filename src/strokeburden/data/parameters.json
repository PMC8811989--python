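{
  "initial_distribution": {
    "prob_by_mrs": [0.1654, 0.2964, 0.2551, 0.1379, 0.0276, 0.0310, 0.0866],
    "low": [0.1489, 0.2668, 0.2296, 0.1241, 0.0248, 0.0279, 0.0779],
    "high": [0.1820, 0.3261, 0.2806, 0.1516, 0.0303, 0.0341, 0.0953]
  },
  "utilities": {
    "short_term": [0.85, 0.78, 0.67, 0.30, 0.11, 0.03],
    "short_low": [0.76, 0.67, 0.53, 0.12, 0.02, 0.00],
    "short_high": [1.00, 0.94, 0.89, 0.42, 0.20, 0.07],
    "long_term": [0.85, 0.80, 0.70, 0.51, 0.30, 0.15],
    "long_low": [0.80, 0.75, 0.53, 0.45, 0.25, 0.00],
    "long_high": [1.00, 0.90, 0.75, 0.65, 0.55, 0.32]
  },
  "costs": {
    "short_term": {
      "medical": [15464, 21901, 40408, 68199, 85578, 140089, 43644],
      "nonmedical": [570, 2112, 5236, 30821, 58569, 82999, 19738],
      "indirect": [14733, 27400, 47534, 36357, 43301, 40781, 39612]
    },
    "short_low": {
      "medical": [5685, 6106, 14837, 44273, 71406, 71464, 3918],
      "nonmedical": [0, 0, 140, 13133, 29341, 46339, 0],
      "indirect": [0, 0, 0, 0, 0, 0, 0]
    },
    "short_high": {
      "medical": [26522, 39353, 51458, 68953, 103792, 161818, 42359],
      "nonmedical": [1140, 4224, 6460, 40867, 74610, 70034, 2627],
      "indirect": [32196, 50593, 87389, 87389, 91988, 87389, 82789]
    },
    "long_term": {
      "medical": [1400, 1400, 1774, 1774, 13715, 17545, 0],
      "nonmedical": [576, 576, 730, 730, 5648, 7225, 0],
      "indirect": [0, 2998, 19855, 27875, 43301, 40781, 0]
    },
    "long_low": {
      "medical": [0, 0, 0, 0, 0, 0, 0],
      "nonmedical": [0, 0, 0, 0, 0, 0, 0],
      "indirect": [0, 0, 0, 0, 0, 0, 0]
    },
    "long_high": {
      "medical": [2800, 2800, 3548, 3548, 27430, 35090, 0],
      "nonmedical": [1152, 1152, 1460, 1460, 11296, 14450, 0],
      "indirect": [0, 5996, 39710, 55750, 86602, 81562, 0]
    }
  },
  "recurrence": {
    "annual_rate": 0.0201,
    "risk_ratio_per_prior_event": 1.39,
    "case_fatality_under65": 0.0866,
    "case_fatality_65plus": 0.2683,
    "no_recurrence_in_first_cycle": true
  },
  "discount": {
    "cost_rate": 0.05,
    "qaly_rate": 0.0,
    "reference_cycle": 1
  },
  "cohort": {
    "n_patients": 13555,
    "total_strokes": 57487,
    "younger_share": 0.2358,
    "male_fraction": 0.6007,
    "age_group_labels": ["<25", "25-34", "35-44", "45-54", "55-64"],
    "age_group_counts": [499, 657, 1649, 3842, 6908],
    "age_group_bounds": [[18, 25], [25, 35], [35, 45], [45, 55], [55, 65]],
    "stroke_type_mix": {"ischaemic": 0.82, "ich": 0.12, "undetermined": 0.06},
    "indirect_cost_age_cutoff": 65
  },
  "age_utilities": {
    "bracket_bounds": [[0, 40], [40, 50], [50, 60], [60, 70], [70, 80], [80, 111]],
    "bracket_labels": ["<40", "40-49", "50-59", "60-69", "70-79", "80-85"],
    "general": [0.85, 0.81, 0.80, 0.80, 0.76, 0.70],
    "stroke": [0.72, 0.65, 0.61, 0.56, 0.46, 0.35]
  },
  "lifetable": {
    "max_age": 110,
    "le_targets": {"21": 61.90, "29.5": 53.15, "39.5": 43.53, "49.5": 34.15, "59.5": 25.19}
  },
  "currency": {"usd_per_aud": 0.784},
  "published": {
    "burden": {
      "5": {
        "qalys_total": 41606.71, "qalys_per_case": 3.07,
        "cost_total": 2022135241, "cost_per_case": 149180,
        "medical_per_case": 52291, "nonmedical_per_case": 18180, "indirect_per_case": 78709,
        "medical_total": 708809346, "nonmedical_total": 246423317, "indirect_total": 1066902578,
        "psa_cost_per_case": 153410, "psa_qalys_per_case": 3.05
      },
      "30": {
        "qalys_total": 200972.80, "qalys_per_case": 14.83,
        "cost_total": 3385762610, "cost_per_case": 249780,
        "medical_per_case": 99690, "nonmedical_per_case": 39624, "indirect_per_case": 110466,
        "medical_total": 1351299747, "nonmedical_total": 537102689, "indirect_total": 1497360174,
        "psa_cost_per_case": 273496, "psa_qalys_per_case": 14.22
      }
    },
    "qaly_loss_rows": [
      {"age_group": "<25",   "n": 499,  "general_lys": 61.90, "stroke_lys": 52.15, "loss_lys": 9.75, "loss_qalys_base": 15.37, "loss_qalys_sensitivity": 16.76},
      {"age_group": "25-34", "n": 657,  "general_lys": 53.15, "stroke_lys": 45.18, "loss_lys": 7.97, "loss_qalys_base": 12.91, "loss_qalys_sensitivity": 14.92},
      {"age_group": "35-44", "n": 1649, "general_lys": 43.53, "stroke_lys": 37.35, "loss_lys": 6.18, "loss_qalys_base": 10.98, "loss_qalys_sensitivity": 12.58},
      {"age_group": "45-54", "n": 3842, "general_lys": 34.15, "stroke_lys": 29.41, "loss_lys": 4.74, "loss_qalys_base": 9.42,  "loss_qalys_sensitivity": 10.47},
      {"age_group": "55-64", "n": 6908, "general_lys": 25.19, "stroke_lys": 21.78, "loss_lys": 3.41, "loss_qalys_base": 7.88,  "loss_qalys_sensitivity": 8.38}
    ],
    "qaly_loss_weighted": {"loss_lys": 4.58, "loss_qalys_base": 9.21, "loss_qalys_sensitivity": 10.11}
  }
}
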