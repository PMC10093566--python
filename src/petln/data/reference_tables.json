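{
  "description": "Cross tables (2x2, histology x test) and printed performance metrics from the original prospective clinical cohort of 101 histologically confirmed thoracic lymph nodes in 37 lung-cancer patients. Cells are (tn, fp, fn, tp) against histology with test positivity value >= cutoff.",
  "n_nodes": 101,
  "n_malignant": 29,
  "n_benign": 72,
  "cross_tables": {
    "suvmax": {"tn": 64, "fp": 8, "fn": 3, "tp": 26, "cutoff": 5.495},
    "ratio_primary": {"tn": 58, "fp": 14, "fn": 6, "tp": 23, "cutoff": 0.457},
    "ratio_liver": {"tn": 59, "fp": 13, "fn": 3, "tp": 26, "cutoff": 1.374},
    "ratio_brainstem": {"tn": 56, "fp": 16, "fn": 5, "tp": 24, "cutoff": 0.749},
    "ratio_lung": {"tn": 53, "fp": 19, "fn": 0, "tp": 29, "cutoff": 4.593}
  },
  "printed_performance": {
    "suvmax": {"cutoff": 5.495, "auc": 0.92, "ci": [0.85, 0.98], "sensitivity": 89.67, "specificity": 88.89, "ppv": 76.47, "npv": 95.52, "accuracy": 89.11},
    "ratio_primary": {"cutoff": 0.457, "auc": 0.86, "ci": [0.78, 0.94], "sensitivity": 79.31, "specificity": 80.56, "ppv": 62.16, "npv": 90.63, "accuracy": 80.20},
    "ratio_liver": {"cutoff": 1.374, "auc": 0.91, "ci": [0.85, 0.98], "sensitivity": 89.66, "specificity": 81.94, "ppv": 66.67, "npv": 95.16, "accuracy": 84.16},
    "ratio_brainstem": {"cutoff": 0.749, "auc": 0.88, "ci": [0.81, 0.95], "sensitivity": 82.76, "specificity": 77.78, "ppv": 60.00, "npv": 91.80, "accuracy": 79.21},
    "ratio_lung": {"cutoff": 4.593, "auc": 0.94, "ci": [0.89, 0.98], "sensitivity": 100.0, "specificity": 73.61, "ppv": 60.42, "npv": 100.0, "accuracy": 81.89},
    "visual_score": {"cutoff": 3, "auc": 0.81, "ci": [0.72, 0.89], "sensitivity": 34.48, "specificity": 95.83, "ppv": 76.92, "npv": 78.41, "accuracy": 78.22},
    "multi_score": {"cutoff": 3, "auc": 0.93, "ci": [0.88, 0.98], "sensitivity": 89.66, "specificity": 86.11, "ppv": 72.22, "npv": 95.38, "accuracy": 87.13}
  },
  "class_distributions": {
    "benign": {
      "suvmax": {"median": 3.45, "range": [1.14, 19.00]},
      "ratio_primary": {"median": 0.22, "range": [0.06, 1.27]},
      "ratio_liver": {"median": 0.92, "range": [0.28, 4.42]},
      "ratio_brainstem": {"median": 0.52, "range": [0.14, 3.88]},
      "ratio_lung": {"median": 3.47, "range": [1.08, 19.00]}
    },
    "malignant": {
      "suvmax": {"median": 11.00, "range": [2.35, 35.55]},
      "ratio_primary": {"median": 0.75, "range": [0.13, 2.42]},
      "ratio_liver": {"median": 3.18, "range": [0.63, 11.19]},
      "ratio_brainstem": {"median": 1.63, "range": [0.51, 8.46]},
      "ratio_lung": {"median": 14.67, "range": [4.60, 50.61]}
    }
  },
  "station_counts": {"2": 6, "4": 21, "5": 8, "6": 3, "7": 27, "10": 18, "11": 16, "12": 2},
  "known_discrepancies": [
    {"feature": "suvmax", "metric": "sensitivity", "printed": 89.67, "recomputed": 89.66, "note": "26/29 = 89.655...% rounds to 89.66; the printed table shows 89.67."},
    {"feature": "ratio_lung", "metric": "accuracy", "printed": 81.89, "recomputed": 81.19, "note": "(53+29)/101 = 81.188...% rounds to 81.19; the printed table shows 81.89 while the accompanying prose says 81.9% - likely a digit transposition."}
  ]
}
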