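"""Extract the 280-feature radiomics vector from one phantom and print the
values of the twelve features used by the shipped malignancy signature.

Extraction runs at the phantom's native grid here; pass the default
FeatureConfig to resample to the standard 0.29 x 0.29 x 0.70 mm grid first.
"""

from vertomics import PhantomParams, make_vertebra_phantom, published_model
from vertomics.features import FeatureConfig, extract_features

case = make_vertebra_phantom(PhantomParams(seed=5), "malignant")
fv = extract_features(
    case.volume, case.truth_mask, FeatureConfig(resample_spacing_mm=None)
)
print(f"extracted {len(fv)} features, all finite\n")
print("signature features (raw, unstandardized):")
for name in published_model().feature_names:
    print(f"  {name:45s} {fv.values[name]:12.4f}")
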