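"""Work with the shipped 12-feature malignancy signature: score standardized
feature vectors, classify at the 0.328 cutoff, and reproduce the diagnostic
statistics implied by the published training-set confusion counts.

The published standardization parameters were never released, so the
signature is applied to *pre-standardized* feature values (z-scores).
"""

from vertomics import ConfusionCounts, classify, diagnostic_metrics, published_model, score

model = published_model()
print(f"{len(model.feature_names)} features, intercept {model.intercept}, cutoff {model.cutoff}\n")

z = {name: 0.0 for name in model.feature_names}
print(f"score at the cohort centre (all z=0): {score(model, z):+.3f} -> {classify(model, z)}")

z["locint_global_intensity_peak"] = 1.5  # bright focus, 1.5 SD above average
z["glszm_small_zone_low_gray_level_emphasis"] = -1.0
print(f"bright-focus, low-SZLGLE case:        {score(model, z):+.3f} -> {classify(model, z)}")

print("\ndiagnostic statistics from the reported training confusion counts")
print("(TP=69, FN=5, FP=19, TN=65):")
for name, m in diagnostic_metrics(ConfusionCounts(tp=69, fp=19, tn=65, fn=5)).items():
    lo, hi = m["ci"]
    print(
        f"  {name:12s} {100 * m['value']:5.1f}%  ({m['num']}/{m['den']})"
        f"  95% CI [{100 * lo:.1f}, {100 * hi:.1f}]"
    )
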