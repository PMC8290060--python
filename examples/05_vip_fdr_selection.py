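"""Select discriminant variables by VIP rank and estimate their FDR.

Runs the whole study in one call: OPLS-DA of the most scattered season
against the rest, top-15 VIP selection, one-way ANOVA across the four
seasons, and the rank-based FDR estimate (p x N / rank with step-up
adjustment, N = 15).
"""

from seasonfuse.pipeline import run_synthetic_study

study = run_synthetic_study(seed=42)
truth = study.ground_truth
planted = set(truth.planted_ms) | set(truth.planted_bin_labels())

print(f"contrast season (most scattered): {study.contrast_season}")
print(f"OPLS-DA R2Y={study.oplsda.r2y:.3f}; "
      f"permutation-validated: {study.permutation.valid}")
print(f"top-15 VIP variables ({sum(v in planted for v in study.top_vip.variable_id)}"
      f"/15 are planted ground-truth variables):")
table = study.fdr.assign(
    planted=[v in planted for v in study.fdr.variable_id])
print(table.to_string(index=False,
                      formatters={"p": "{:.2e}".format,
                                  "fdr_raw": "{:.2e}".format,
                                  "fdr_adj": "{:.2e}".format}))
print(f"max adjusted FDR among selected variables: {study.fdr.fdr_adj.max():.4f} "
      "(<= 0.05 means every selected variable is a credible seasonal marker)")
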