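{
  "feature_names": [
    "morph_approximate_volume",
    "morph_major_axis_length",
    "locint_global_intensity_peak",
    "stat_minimum_gray_level",
    "ih_mean",
    "ih_robust_mean_absolute_deviation",
    "glcm_joint_entropy",
    "glszm_small_zone_low_gray_level_emphasis",
    "ngldm_high_dependence_emphasis",
    "log1mm_locint_local_intensity_peak",
    "log1mm_stat_75th_percentile",
    "log1mm_ih_maximum_histogram_gradient"
  ],
  "coefficients": [
    -0.483,
    -0.544,
    0.837,
    0.745,
    0.730,
    0.104,
    -0.088,
    -0.994,
    0.329,
    -0.444,
    -0.105,
    -0.051
  ],
  "intercept": -0.176,
  "cutoff": 0.328,
  "standardization_mean": null,
  "standardization_sd": null
}
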