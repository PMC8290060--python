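"""Generate a synthetic seasonal harvest study.

Builds the sample design (3 replicates x 4 seasons x 2 years), matching
climate covariates, an LC-HRMS feature table with planted seasonal effects
and blank-only background features, and 1D NMR spectra with planted peaks.
"""

from seasonfuse import synthetic

design = synthetic.generate_design(n_per_season=3, n_years=2, seed=42)
climate = synthetic.generate_climate(design, seed=43)
matrix, truth_ms = synthetic.generate_ms_features(
    design, n_features=200, n_planted=10, n_blank=10, effect_size=3.0, seed=44)
spectra, truth_nmr = synthetic.generate_nmr_spectra(
    design, n_peaks=30, n_planted=5, effect_size=3.0, seed=45)

print(f"design: {len(design)} samples, "
      f"{design.season.value_counts().to_dict()}")
summer = climate.merge(design, on="sample_id").groupby("season").temperature.mean()
print(f"mean temperature by season (degC): "
      f"{ {k: round(v, 1) for k, v in summer.items()} }")
print(f"MS table: {matrix.n_features} features x {len(matrix.sample_ids)} samples; "
      f"{len(truth_ms.planted_ms)} planted, {len(truth_ms.blank_ms)} blank-only")
print(f"NMR: {len(spectra)} spectra of {len(spectra[0].ppm)} points; "
      f"planted peaks at {sorted(round(c, 2) for c in truth_nmr.planted_nmr_peaks)} ppm")
# The planted sets are the ground truth every later stage is judged against:
# the blank filter should remove exactly the blank features, and the
# discriminant-selection stage should recover the planted variables.
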