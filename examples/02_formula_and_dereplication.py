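"""Elemental formula prediction and exact-mass dereplication.

Predicts CHNOPS compositions for a protonated flavan-3-ol monomer ion,
classifies a sugar anomer from its coupling constant, and matches synthetic
features against the packaged compound library.
"""

from seasonfuse import synthetic
from seasonfuse.formulas import (classify_anomeric, dereplicate, hits_to_frame,
                                 predict_formula, theoretical_mz)
from seasonfuse.ms_features import remove_blank_features

# A catechin-like [M+H]+ ion observed at m/z 291.0860:
candidates = predict_formula(291.0860, "[M+H]+", tolerance_ppm=5.0)
print(f"{len(candidates)} formula candidates within 5 ppm; best few:")
for c in candidates[:3]:
    print(f"  {c.formula:<14} {c.ppm_error:+.2f} ppm  RDBE {c.rdbe:.0f}")
best_cho = next(c for c in candidates
                if c.counts[2] == c.counts[4] == c.counts[5] == 0)
print(f"best CHO-only candidate: {best_cho.formula} "
      f"({best_cho.ppm_error:+.2f} ppm) — the flavan-3-ol composition")

# Anomeric configuration from the H-1/H-2 coupling constant:
for j in (7.7, 3.8):
    print(f"J = {j} Hz -> {classify_anomeric(j)} anomer")

# Dereplicate a synthetic feature table against the toy library:
design = synthetic.generate_design(3, 2, 42)
matrix, _ = synthetic.generate_ms_features(design, 200, 10, 10, 3.0, 44)
matrix.features.loc[0, "mz"] = theoretical_mz("C21H20O12", "[M+H]+")  # spike in
filtered, removed = remove_blank_features(matrix)
hits = hits_to_frame(dereplicate(filtered, synthetic.generate_reference_library()))
print(f"blank filter removed {len(removed)} background features")
print(f"{len(hits)} annotation hits; isomeric library records share one feature:")
print(hits.head(5).to_string(index=False))
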