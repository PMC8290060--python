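"""Preprocess 1D NMR spectra and reduce them to 0.04 ppm buckets.

Shows the default chain (asymmetric-least-squares baseline, Gaussian
broadening, Savitzky-Golay smoothing, largest-peak normalization) and the
bucket matrix that becomes the NMR block of the fused data set.
"""

import numpy as np

from seasonfuse import synthetic
from seasonfuse.nmr import bin_matrix, preprocess

design = synthetic.generate_design(3, 2, 42)
spectra, truth = synthetic.generate_nmr_spectra(design, n_peaks=30,
                                                n_planted=5, seed=45)
processed = [preprocess(s) for s in spectra]
bins = bin_matrix(processed, ppm_min=0.0, ppm_max=10.0, width=0.04)

print(f"binned matrix: {bins.shape[0]} samples x {bins.shape[1]} buckets "
      f"(0-10 ppm at 0.04 ppm -> 250 buckets)")
print(f"max normalized intensity: {processed[0].intensity.max():.3f} "
      "(largest peak scaled to 1)")

labels = design.season.to_numpy()
for label, (season, d) in truth.planted_bin_labels().items():
    col = bins[label].to_numpy()
    ratio = col[labels == season].mean() / col[labels != season].mean()
    print(f"bucket {label} ppm (planted for {season}): "
          f"in-season / off-season intensity ratio {ratio:.2f}")
# Ratios near exp(3 * 0.25) ~ 2.1 confirm the planted amplitude modulation
# survives preprocessing and binning.
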