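# Methods

## Scope and model

`ihcgate` reimplements a digital-immunohistochemistry triage analysis for
fluorescence-guided-surgery (FGS) targets in vulvar squamous cell
carcinoma: per-cell DAB intensity classification on H-DAB slides, region
H-scores, group medians and tumor-to-background ratios (TBRs),
nonparametric group comparisons, a four-criterion target gate, and
per-patient favorability classification.  Since the original cohort's
pixel data were never deposited, the package ships a synthetic-slide
generator whose statistical and spatial structure mirrors the published
cohort; all pixel-level validation is against that generator's ground
truth, and the published summary statistics (median H-scores per marker
and group, narrative pattern/localization labels, per-patient
favorability counts) are carried as plain data in `ihcgate.reference`.

## Measurement chain

1. **Optical density.** `OD = -log10(max(I, 1)/255)` per RGB channel.
   The clamp at intensity 1 bounds OD at ~2.407; stain contributions add
   linearly in OD (Beer–Lambert).
2. **Stain separation.** Each pixel's OD vector is projected onto the
   hematoxylin and DAB absorbance directions by unregularized least
   squares; negative concentrations are clamped to zero.  Default vectors
   are the standard published H-DAB directions, hematoxylin
   ≈ (0.651, 0.701, 0.290) and DAB ≈ (0.269, 0.568, 0.778), unit-norm;
   they are configurable because scanner calibration varies.  The two
   directions are ~37° apart (condition number ≈ 3), so 8-bit quantization
   noise of ~0.003 OD can amplify to ~0.01 OD in the unmixed channels —
   that is the round-trip tolerance used in tests.
3. **Nucleus detection.** Gaussian smoothing (σ = 1.5 px) of the
   hematoxylin channel, fixed OD threshold 0.1 (Otsu optional), hole
   filling, removal of components under 7 µm², then a watershed split on
   the distance transform with peaks at least 3 µm apart (one nucleus
   radius).  These defaults resolve ≥ 95% of generated nuclei at both
   0.5 and 1.0 µm/px.
4. **Cell expansion.** Nuclei are grown by 5 µm; contested pixels go to
   the nearest nucleus (`skimage.segmentation.expand_labels`); masks are
   clipped to the annotation polygon and are pairwise disjoint.  No
   membrane/cytoplasm compartmentalization is attempted — the mean DAB OD
   over the whole expanded cell is the per-cell measurement.
5. **Classification.** Intensity class = number of thresholds ≤ mean DAB
   OD, thresholds (0.2, 0.4, 0.6) OD.  The lower-inclusive band
   convention is applied identically in the generator and the classifier;
   the thresholds are exposed in every config because each H-score
   depends on them.

## Scoring and statistics

* H-score = 1·pct₁ + 2·pct₂ + 3·pct₃ over a region's cells; categories
  low [0, 50), medium [50, 250), high [250, 300] (the printed bands
  overlap at the boundaries; the half-open convention is ours, with the
  top band closed at 300).
* A section's group value is the arithmetic mean of its same-tissue-type
  annotation H-scores; group summaries are median/min/max over sections
  (even counts: midpoint).  Sections missing a marker are excluded and n
  is reported.
* TBR = unrounded lesion median / unrounded healthy median; reported at
  one decimal, half away from zero; `favorable` (> 2) and `inverse` (< 1)
  are derived from the unrounded value.  Computed this way, 32 of the 36
  published TBR cells reproduce exactly; the four that do not
  (EGFR and MRP1 in HPV-independent VSCC, FRα and uPAR in HPV-dependent
  VSCC) are internally inconsistent with their own printed medians —
  most plausibly because the upstream medians were themselves rounded —
  and are recorded in `reference.KNOWN_TBR_DISCREPANCIES` rather than
  matched.
* Mann–Whitney U is computed from midranks; two-sided
  p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.  Method ladder: exact
  enumeration of the rank-configuration null (dynamic programming) when
  the pooled sample is tie-free with ≤ 25 observations; exhaustive
  permutation over all group splits when feasible (≤ 2·10⁵ splits);
  otherwise a tie-corrected normal approximation with continuity
  correction.  A seeded Monte-Carlo permutation mode exists for large
  tied samples.  The original analysis's exact-vs-asymptotic choice is
  unknowable (only stars were published), so the method is always
  reported alongside p.  The six predefined pairs are tested in fixed
  order with no multiple-testing adjustment, matching the exploratory
  design.

## The gate

Criterion 1 (TBR ≥ 2 against healthy *and* stromal medians) falls back to
healthy-only with an explicit `stroma_available=False` flag when no
stromal annotations exist — the source tabulates no stromal H-scores.
Criterion 2 is median ≥ 25 in every lesion group.  Criterion 3
(homogeneous expression "throughout the tumor") is evaluated on the
malignant groups only: precursor lesions are physiologically
basal-restricted even for the flagship marker, so an all-groups reading
would reject every candidate and contradicts the published verdict.
Criterion 4 requires membrane localization.  Criteria 3–4 are qualitative
in origin; the gate consumes curated `MarkerMetadata` by default and can
instead compute a quantitative surrogate (`--computed-pattern`):
positive fraction (< 0.05 → absent), a join-count z-score of
positive/negative labels on the 6-nearest-neighbor cell graph against a
label-permutation null (> 3 → patchy), and the ratio of median basal
depth of positive vs all cells (< 0.5 → restricted).

Patient classification follows the favorability rule: per section, each
lesion tissue's mean H-score is divided by the same section's healthy
mean; green iff all present ratios > 2, orange iff the malignant ratio
≤ 2 but the premalignant ratio > 2, red iff all ratios ≤ 1.  Ratios
stranded in (1, 2] without qualifying as orange are not covered by the
published legend; they are labeled `unfavorable` and counted with red in
cohort fractions (the conservative reading).  The source text assigns the
78% figure to different HPV strata in two places; the package follows the
internally consistent reading (78% = 7/9 HPV-independent,
40% = 4/10 HPV-dependent).

## Synthetic-data generator

What it emulates: the reported section counts per group; carcinoma
sections carrying adjacent precursor and healthy tissue as concentric
bands (tumor core, precursor rim, healthy margin — 9/16 HPV-independent
and 10/13 HPV-dependent sections, matching the reported evaluable
fractions); class-fraction profiles whose expected H-score
100·(p₁ + 2p₂ + 3p₃) is calibrated to any target median (maximum-entropy
tie-break: the Gibbs solution p_k ∝ e^{λk}); spatial patterns
(homogeneous i.i.d.; patchy via Gaussian-smoothed white noise thresholded
at the positive-fraction quantile, correlation length `patch_scale_um`;
basal-restricted with positives confined below normalized depth 0.4;
linear-gradient; absent); hard-core nucleus placement (min separation
7 µm) at 3,000 cells/mm²; and Beer–Lambert rendering with per-stain
Gaussian OD noise.

Key defaults (all configurable): 2048×2048 px at 0.5 µm/px, nucleus
radius 3 µm (hematoxylin disc OD 0.7), DAB painted over an 11 µm-radius
disc per cell with contested pixels owned by the nearest nucleus — the
paint radius deliberately exceeds the 5 µm measurement expansion so a
measured mask never reaches unpainted background, and the ownership rule
matches the classifier's contested-pixel rule.  True per-cell DAB OD is
drawn uniformly inside the class's threshold band (ceiling 1.2 OD) with a
0.02-OD guard margin, making ground-truth classes exactly recoverable in
the noiseless limit; negative cells carry zero DAB.

What it does **not** emulate: real histology texture, stromal fibers,
folds, out-of-focus blur, scanner color variation, overlapping nuclei in
thick sections, or biologically realistic inter-section H-score
dispersion beyond counting statistics.  Passing pixel-level tests
therefore demonstrates the *software chain's* correctness, not the
robustness of the measurement on real tissue.  The per-section H-score
variance of the generator (pure multinomial) is much smaller than the
published min–max ranges, so simulated Mann–Whitney stars are not
comparable to the published figure and are not asserted anywhere.

A sentence in the source describes HSIL adjacent to carcinoma as staining
*more* intensely than isolated HSIL while printing averages that imply
the opposite; the generator takes no side — adjacent-region profiles are
freely configurable per tissue type.

## Problem sizes

Module tests run on sections of 300–800 px.  The end-to-end recovery
test simulates the full 69-section cohort at 1.0 µm/px on 830×830 px
sections (~0.67 mm², hence ~2,000 cells/section at 3,000 cells/mm²),
plain (unbanded) sections so each section contributes a single
~2,000-cell annotation, with OD noise 0.02; recovery tolerance is
±max(15%, 10 H-score units) per group median, and all lesion TBRs must
exceed 2.  The pixels-to-verdict robustness check uses 50 seeded
replicates of a 5-section mini-cohort (300×300 px) per marker profile.

## Known limitations

* The intensity thresholds (0.2/0.4/0.6 OD) are a field convention, not a
  published value of the original workflow; absolute H-scores shift with
  them, though TBRs are fairly insensitive because both numerator and
  denominator move together.
* Stromal false positives of the detector are not modeled (the generator
  places no stromal cell population by default); the original authors
  note a slight epithelial-cell overestimation in stromal areas that this
  package can only document, not reproduce.
* `homogeneity_score` needs ≥ 50 cells and a basal-axis depth column to
  distinguish "restricted" from "homogeneous"; measured (non-synthetic)
  tables without depth fall back to the clustering and positivity terms.
* Exact Mann–Whitney is limited to tie-free pooled samples of ≤ 25; real
  H-score data with heavy ties at 0 route to the permutation or normal
  branch, which is reported in the output.
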