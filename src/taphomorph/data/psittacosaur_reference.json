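{
  "description": "Published reference values from the 28-specimen Lujiatun psittacosaur cranial landmark analysis. The eigenvalue table lists the first eight principal components of the shape-space PCA (shape-variance units), their proportion of total variance and the cumulative variance, as originally printed. Half-widths are the reported 95% confidence-interval half-widths for PC1-PC4 scores.",
  "n_specimens": 28,
  "n_landmarks_collected": 56,
  "n_landmarks_retained": 44,
  "n_components_interpreted": 4,
  "confidence_multiplier": 1.96,
  "eigenvalue_table": [
    {"pc": 1, "eigenvalue": 8.56e-03, "proportion_pct": 27.9, "cumulative_pct": 27.9},
    {"pc": 2, "eigenvalue": 5.71e-03, "proportion_pct": 18.6, "cumulative_pct": 46.5},
    {"pc": 3, "eigenvalue": 2.77e-03, "proportion_pct": 9.04, "cumulative_pct": 55.6},
    {"pc": 4, "eigenvalue": 2.34e-03, "proportion_pct": 7.64, "cumulative_pct": 63.2},
    {"pc": 5, "eigenvalue": 2.12e-03, "proportion_pct": 6.92, "cumulative_pct": 70.1},
    {"pc": 6, "eigenvalue": 1.67e-03, "proportion_pct": 5.45, "cumulative_pct": 75.6},
    {"pc": 7, "eigenvalue": 1.33e-03, "proportion_pct": 4.35, "cumulative_pct": 79.9},
    {"pc": 8, "eigenvalue": 8.29e-04, "proportion_pct": 2.70, "cumulative_pct": 82.6}
  ],
  "reported_ci_halfwidths": {"1": 0.181, "2": 0.148, "3": 0.103, "4": 0.095}
}
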