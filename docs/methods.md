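# Methods

This note documents the models, algorithms, defaults and design choices
behind `seasonfuse`, and what the synthetic-data tests do and do not
establish about real data.

## Problem setting

A seasonal metabolomics study observes the same plant species harvested
across the four seasons (here: n replicates per season over several years)
on two instruments: untargeted LC-HRMS, yielding an aligned table of
features (m/z, retention time, per-sample peak areas, one solvent-blank
column per polarity), and ¹H NMR, yielding one intensity trace per extract.
The questions are (i) whether season explains the chemical variation and
(ii) which variables — MS features or NMR buckets — discriminate the
seasons, with multiplicity control over the selected set.

## LC-HRMS curation

**Blank removal.** A feature is background iff
mean(sample areas) / blank area < ratio threshold.  The threshold defaults
to 3, the conventional blank-fold-change in untargeted metabolomics; it is
not derivable from first principles and is exposed in configuration.  A
blank area of exactly 0 retains the feature unconditionally (no background
evidence).  The mean, rather than per-sample comparison, is used; this is
configurable in the sense that callers can pre-aggregate differently.

**Formula prediction.** For an ion at m/z *m* with adduct [M±H]±, the
neutral target mass is m ∓ 1.007276 Da (proton mass, i.e. hydrogen minus
electron; [M+Na]⁺ and [M+HCOO]⁻ are supported but disabled by default).
The search enumerates C, N, O, P, S counts inside per-element bounds
(default C≤70, H≤110, N≤6, O≤35, P≤3, S≤3 — sized to cover proanthocyanidin
pentamer ions near m/z 1441 without combinatorial blow-up), solves for the
hydrogen count from the mass remainder (valid because the tolerance window
is far narrower than one hydrogen mass), and filters candidates by:

* RDBE = C + 1 + (N+P)/2 − H/2 within [0, 40] **and** integer on the
  neutral molecule (even-electron ions), equivalently H+N+P even;
* element ratios 0.1 ≤ H/C ≤ 6, N/C ≤ 4, O/C ≤ 3, P/C ≤ 2, S/C ≤ 3.

The ppm and absolute tolerances (defaults 5.0 ppm, 0.001 m/z) combine as
the *larger* of the two — an "A or B" acceptance window; "smaller" is
available.  Candidates sort by |ppm error|, ties by fewer heteroatoms then
lexicographic counts.  The isotope-pattern filter is an optional hook that
acts only when an observed M+1 relative intensity is supplied: aligned
feature tables are deisotoped upstream and carry no envelope, so by default
this third heuristic is a no-op.  Note that an exhaustive CHNOPS search can
rank an exotic heteroatom-rich composition above the chemically sensible
CHO formula on mass error alone (e.g. C10H19N4PS2 beats C15H14O6 at
m/z 291.0860 by 0.5 ppm); mass accuracy bounds are therefore reported for
the best candidate, while annotation relies on the library.

**Dereplication** emits one hit per (feature, polarity-compatible adduct,
library record) within tolerance.  Exact mass cannot separate isomers, so a
feature may receive several hits; both members of an isomeric pair are
reported.  The packaged library is a small curated stand-in for a
commercial natural-products database: ~40 CHNO compounds spanning
proanthocyanidins (A- and B-type, monomer to pentamer), galloylquinic and
galloylshikimic acid ladders, pentacyclic triterpenes, glycosylated
flavonoids, cinnamic and phenolic acids, and triterpenic saponins.

**Anomeric configuration**: a sugar anomeric proton with ³J(H1,H2)
coupling > 5.0 Hz is assigned β (trans-diaxial), 0–5.0 Hz α; the boundary
value 5.0 belongs to α.

## NMR preprocessing and bucketing

The default chain is baseline → broaden → smooth → normalize → bin.  The
order is a package choice (the individual steps commute only
approximately).

* **Baseline**: asymmetric least squares with a second-difference Whittaker
  penalty — minimise Σ wᵢ(yᵢ−zᵢ)² + λ‖D₂z‖², weights `asymmetry` (default
  0.01) above the baseline and 1−asymmetry below, λ default 1e5, 10
  iterations or convergence.
* **Gaussian broadening**: convolution with a unit-area Gaussian of
  σ = GB/spectrometer frequency (default 1 Hz at 500 MHz → 0.002 ppm).
* **Smoothing**: Savitzky–Golay, window 11 points, order 3.
* **Normalization**: division by the largest absolute intensity.
* **Bucketing**: half-open buckets [low, low+w) of width w = 0.04 ppm; the
  bucket value is the *mean* of point intensities (a "sum" variant is
  available behind a switch; the mean is the primary interpretation of an
  averaged-sum option).  Empty buckets are 0.  0–10 ppm yields 250 buckets,
  0–13 ppm yields 325.  No solvent-region exclusion is applied by default.

## Fusion

Each block (samples × variables, MS or NMR) is scaled by S = Σⱼ sⱼ, the sum
of per-variable sample SDs (ddof = 1, configurable), every cell divided by
S.  After scaling, each block's SDs sum to exactly 1, so the fused,
column-concatenated matrix carries equal total variation per block
regardless of the instruments' raw intensity scales; the scaling is
equivariant under global rescaling of a block.  SDs are computed over all
samples (not per season).  Row sum-normalization and a mean-intensity
variable filter (keep top 75% by column mean, boundary ties retained) are
provided for the web-platform-style re-analysis recipe and are off by
default.

## Chemometrics

**Pareto scaling** x′ᵢⱼ = (xᵢⱼ − x̄ⱼ)/√sⱼ; constant columns map to zero.

**PLS-DA**: class labels are one-hot encoded and column-centered; NIPALS
with X- and Y-deflation extracts components; R²X and R²Y come from the
deflation residuals.  Scores are mutually orthogonal (checked to 1e-8), and
for a single response the first weight vector is the normalized X′y
direction.  Predictions agree with an independent PLS2 implementation
(scikit-learn's `PLSRegression`) to 1e-6; that library is used only as a
test oracle, never in the pipeline.

**OPLS-DA** handles a binary contrast: w ∝ X′y; orthogonal components
w_o ∝ p − (w′p)w are removed from X before the predictive component(s), so
predictive and orthogonal scores are uncorrelated and, with zero orthogonal
components, the model reduces to single-component PLS-DA.

**Cross-validation**: stratified k-fold (default 7 folds, the chemometrics
software convention; automatically reduced to the smallest class size by
the pipeline, since n = 6 per season cannot support 7 stratified folds),
Q² = 1 − PRESS/SS with held-out predictions against the one-hot response.

**Permutation validation** (default 100 permutations): for each permuted
labelling, refit + cross-validate; regress Q² (and R²Y) on the absolute
correlation between permuted and true assignments over the permuted points
plus the observed point at correlation 1.  Valid ⇔ Q² intercept < 0 and
observed Q² > max permuted Q².

**VIP**: VIPⱼ = √( p · Σₐ (wⱼₐ/‖wₐ‖)² SSYₐ / Σₐ SSYₐ ) over predictive
components, so Σⱼ VIPⱼ² = p.  Selection takes the top k = 15 by VIP,
boundary ties broken by input order.  The selection model is the one-vs-rest
OPLS-DA of the *most scattered* season; PLS-DA VIPs are also exported.

**Most scattered season** is operationalized as the season whose samples
have the largest mean squared distance from the overall centroid of the
2-component PLS-DA score plot.  This captures what "scattered" means
visually — a group that both spreads and breaks away from the tight cluster
of the rest.  Pure within-class scatter was rejected: at n = 6 per season
it is fluctuation-dominated and unstable.

## Significance and FDR

For the selected variables, one-way ANOVA across the four seasons gives
per-variable p-values (Kruskal–Wallis available); Tukey HSD provides
pairwise contrasts.  The rank-based FDR over the tested set of size N
(= 15 after selection, deliberately *not* the full variable count) is
FDRᵢ = p₍ᵢ₎·N/i for ascending p, made monotone by the step-up adjustment
(running minimum from the largest rank downward, capped at 1) — the
Benjamini–Hochberg adjusted value; both raw and adjusted values are
reported, significance at adjusted FDR ≤ α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions used throughout the tests:
3 replicates × 4 seasons × 2 years (n = 6/season), 200 MS features with 10
planted seasonal effects and 10 blank-only features, 30 NMR peaks with 5
planted (15 planted variables in total), standardized effect size d = 3.

* **MS areas** are log-normal: per-feature log-mean drawn N(ln 1e5, 1.4)
  (log-normal abundance distribution — few dominant peaks, many small),
  shared within-season log-SD 0.3 (~30% CV, typical for biological
  replicates of bulk extracts).  A planted feature adds d·σ on the log
  scale in exactly one season.
* **Two compound families**: planted variables split 2:1 between two anchor
  seasons on opposite sides of the harvest cycle (majority family peaking
  in winter, minority in summer), mirroring the seasonal behaviour of
  phenolics versus triterpenes/saponins in tannin-rich extracts.  Planted
  features draw baseline intensity from the abundant upper decade
  (2e6–1e7): seasonal markers reported in such studies are major
  constituents, and variance-weighted VIP selection cannot see minor ones.
  A uniform-random season assignment was deliberately rejected: with one
  one-vs-rest contrast only ~a quarter of planted variables respond, their
  point-biserial correlation (~0.26 at d = 3) falls below the maximum
  chance correlation among ~425 noise variables at n = 24, and the top-15
  necessarily fills with noise — no noise level rescues that geometry.
* **Blank structure** is guaranteed, not merely probable: biological
  features get blank area = mean(sample areas)/U(15, 100) (ratio ≥ 15) and
  blank features get sample areas = blank·U(0.05, 0.6) (ratio ≤ 0.6), so
  the ratio-3 filter has a deterministic correct answer and the filter's
  sensitivity/specificity tests are exact.
* **NMR spectra** are sums of Lorentzian peaks (HWHM 0.006 ppm) in the
  aliphatic (0.5–2), sugar/organic-acid (3–6) and aromatic (6–9 ppm)
  regions, on a random quadratic baseline (coefficient SD 0.05) with
  additive Gaussian noise (SD 0.003), amplitudes log-normal (σ = 0.25).
  Three guarantees keep the ground truth meaningful: peak centers are at
  least three bucket widths apart (resolved resonances — a colliding peak
  would corrupt the planted-bucket label); planted peaks sit in the middle
  half of their bucket (an edge-straddling center genuinely belongs to two
  buckets); and the normalization reference resonance (amplitude 3) stays
  the largest peak even when planted peaks are seasonally elevated —
  otherwise largest-peak normalization divides by the planted peak itself
  and erases its own effect.
* **Climate** covariates are season-conditional Gaussians with
  Cerrado-like contrasts (hot rainy summer, long dry cool winter), clipped
  to physical ranges.  They annotate score plots; no model is fitted to
  them.

What passing tests show: the pipeline's operations are correct (verified
against closed forms, brute-force oracles and independent library
implementations), and under the stated conditions the full chain recovers
planted discriminant variables with low FDR.  What they do not show:
performance under retention-time drift, batch effects, missing values,
peak-shape pathologies, correlated metabolite families, or effect sizes and
replication below the stated conditions.  At d = 3 and n = 6 the
per-variable ANOVA tail P(p > 0.05) is ~2–3%, so the maximum adjusted FDR
over 15 selected variables exceeds 0.05 in roughly one seed in ten — an
irreducible property of these sample sizes, not of the implementation.

## Numerical choices and degenerate inputs

Sample SDs use ddof = 1 throughout.  All-constant blocks, all-zero spectra,
zero-sum rows and constant test variables raise degenerate-input errors
rather than producing NaNs.  NIPALS converges at ‖Δw‖ < 1e-12 (≤500
iterations).  Seeds: every generator and every stochastic stage takes an
explicit seed; the pipeline derives stage seeds as base+0…base+4 and
records the seed plus a configuration hash in every output table.  File
reloads during resumed runs use round-trip float parsing so resumed and
fresh runs are byte-identical.

## Known limitations

No isotope-envelope simulation or scoring; no retention-time modelling; no
2D NMR processing (J-resolved projections enter as ordinary 1D spectra);
single-block OPLS only (no multi-block or kernel variants); FDR is the
rank-based estimate over the selected set, not a resampling-based estimate;
the compound library is a toy, so annotation coverage on real data requires
supplying a real library CSV.
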