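"""Image normalization: resampling, binarization, padding, augmentation.

Simulates an anisotropic multi-label scan, runs it through the preprocessing
chain the classifier expects, and shows that augmentation preserves the
binary value set and the labels.
"""

import numpy as np

from pelvistrat.preprocess import (
    ImageVolume,
    augment_epoch,
    binarize_roi,
    normalize_clinical,
    ClinicalBounds,
    pad_to_common,
    resample_isotropic,
)
from pelvistrat.phantom import ClinicalCovariates, LabeledCase

rng = np.random.default_rng(0)

# a 3 mm-spacing label map with two bone classes (1 = ilium, 2 = sacrococcyx)
labels = rng.integers(0, 3, (40, 40, 30)).astype(np.int16)
scan = ImageVolume(values=labels, spacing_mm=(3.0, 3.0, 3.0))

iso = resample_isotropic(scan, 1.5, interpolation="nearest")
print(f"resampled {scan.values.shape} @3.0mm -> {iso.values.shape} @1.5mm")

mask = binarize_roi(iso)
print(f"binarized: value set {sorted(np.unique(mask.values))}, "
      f"{int(mask.values.sum())} bone voxels")

padded = pad_to_common([mask, ImageVolume(values=np.zeros((90, 90, 70), np.uint8), spacing_mm=(1.5,) * 3)])
print(f"padded to common shape {padded[0].values.shape}; bone voxels unchanged: "
      f"{int(padded[0].values.sum()) == int(mask.values.sum())}")

bounds = ClinicalBounds(bmi_min=18.0, bmi_max=32.0)
vec = normalize_clinical(ClinicalCovariates(bmi=25.0, male=1, neoadjuvant=0), bounds)
print(f"clinical vector (BMI, male, neoadjuvant) normalized to (0,1): {np.round(vec, 3)}")

case = LabeledCase("demo", (mask.values > 0).astype(np.uint8), (1.5,) * 3,
                   ClinicalCovariates(bmi=25.0, male=1, neoadjuvant=0), label=1, latent_p=0.8)
variants = augment_epoch([case], rng)
print(f"augmentation: 1 case -> {len(variants)} variants per epoch, "
      f"labels {[v.label for v in variants]}, all binary: "
      f"{all(set(np.unique(v.volume)) <= {0, 1} for v in variants)}")
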