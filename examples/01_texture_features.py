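"""Compute GLCM texture features for a smooth and a rough ROI.

Builds two small textured patches — one spatially smooth (long correlation
length), one rough — quantizes each to 8 gray levels, and prints the
rotation-invariant features that react to spatial coherence. Smooth regions
score higher on homogeneity and autocorrelation; rough ones on contrast and
dissimilarity.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from fmritex import quantize, roi_glcms, rotation_invariant_features
from fmritex.volumes import ROIPatch

rng = np.random.default_rng(0)

for name, sigma in [("rough", 0.5), ("smooth", 2.5)]:
    acc = []
    for _ in range(20):
        field = gaussian_filter(rng.standard_normal((16, 16)), sigma,
                                mode="wrap")
        patch = ROIPatch(slice_index=0, values=field,
                         inside=np.ones((16, 16), bool))
        acc.append(rotation_invariant_features(roi_glcms(quantize([patch],
                                                                  8))))
    mean = {k: np.mean([f[k] for f in acc]) for k in acc[0]}
    print(f"{name:7s} homogeneity={mean['homogeneity']:.3f} "
          f"autocorrelation={mean['autocorrelation']:.2f} "
          f"contrast={mean['contrast']:.3f} "
          f"dissimilarity={mean['dissimilarity']:.3f}")

print("\nSmooth fields concentrate co-occurrences near the GLCM diagonal,")
print("raising homogeneity/autocorrelation and lowering contrast.")
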