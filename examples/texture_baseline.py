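"""The 92-feature texture baseline on one image.

Extracts the six standard texture families from a synthetic image and prints
a few interpretable values.  These features describe the intensity histogram
and gray-level spatial arrangement — the comparison baseline for the
topology-based features.
"""

import numpy as np

from bettipath import ClassRecipe, make_image, texture_features, to_grayscale

img = make_image(
    ClassRecipe("demo", n_blobs=8, n_rings=3), (256, 256), np.random.default_rng(0)
)
feats = texture_features(to_grayscale(img))

print(f"total features: {len(feats)}")
for name in (
    "firstorder_Mean",
    "firstorder_Entropy",
    "glcm_Contrast",
    "glcm_Correlation",
    "glszm_ZonePercentage",
    "ngtdm_Coarseness",
):
    print(f"{name:28s} {feats[name]:12.4f}")
print()
print("Mean/Entropy summarize the histogram; GLCM Contrast/Correlation the")
print("pairwise gray-level arrangement; ZonePercentage the granularity of")
print("constant-intensity zones; Coarseness the local intensity uniformity.")
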