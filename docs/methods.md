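# Methods

`musemargin` implements a quantitative analysis chain for deep-UV
surface-excitation fluorescence (MUSE) images of fresh breast surgical
specimens, aimed at intraoperative margin assessment: does the excised
surface carry invasive carcinoma?  The chain mirrors how such images are
acquired and read — mosaic tiles are shading-corrected, stitched and
contrast-enhanced, nuclei are segmented on the red channel (propidium
iodide stains nuclei and emits yellow-red; eosin Y stains cytoplasm and
connective tissue and emits green-yellow), and the nuclear-to-cytoplasm
area ratio (N/C) is scored on a two-level patch grid and used as the
classifying statistic.

## Pipeline model and assumptions

**Shading correction** (`preprocess`).  A single oblique deep-UV LED
illuminates each field unevenly; the distortion is modelled as a smooth
multiplicative gain acting on the saturation (S) and value (V) channels of
the HSV representation, leaving hue — the colour split between the two
stains — untouched.  The gain is estimated retrospectively from the tile
stack itself: the per-pixel median across tiles suppresses tissue (which
moves from field to field) and keeps the static illumination pattern; a
wide Gaussian blur (sigma = 1/8 tile width by default) removes residual
texture; the field is normalised to spatial mean 1.  This is a deliberately
simple, self-contained estimator of the same retrospective flat-field idea
used in microscopy practice; it assumes at least 4 tiles and tissue that is
not spatially static across the stack.  Estimation is per tile set (per
specimen), recorded in the output metadata.

**Stitching** (`stitch`).  The stage is a calibrated XY translator, so the
registration model is translation-only.  Pairwise offsets between grid
neighbours are refined over an integer search window (default ±8 px around
the nominal stage offset) by maximising the Pearson correlation of the
V-channel overlap; a quadratic fit around the peak provides sub-pixel
estimates on request, but offsets are rounded to integers before
compositing so tiles are never resampled (interpolation would blur the
nuclei segmentation relies on).  Redundant pairwise links are reconciled by
weighted least squares with the first tile pinned at the origin; links with
correlation below 0.3 (or degenerate, constant overlaps) are replaced by
the nominal stage offsets at low weight, which also keeps the link graph
connected.  Blending uses linear feather weights (distance to the tile
border, floored at one so border pixels still contribute); where all
contributing tiles agree the blend reproduces their common value exactly
after re-quantisation.

**Contrast enhancement** (`preprocess.equalize_rg`).  Global histogram
equalization of the R and G channels of the stitched mosaic, computed over
in-tissue pixels (V above 2% of range so the dark background does not
dominate) and applied as one monotone lookup table per channel; B is
untouched.  This serves the *visual* output: quantification deliberately
runs on the pre-equalization mosaic.  The reason is structural: the
segmentation threshold is defined as 70% of the mean of the 1% brightest
red pixels, a rule that presumes a raw histogram in which nuclei form a
small bright tail.  After equalization the red histogram is flat by
construction, the same rule admits roughly the top 30% of pixels, and
nuclear/cytoplasm edges in dense tumor are compressed to a few grey
levels — the measured N/C values stop resembling nuclear area fractions.
On the raw mosaic the rule is selective and the measured class means land
where tissue-level nuclear fractions put them.

**Nuclei segmentation** (`ncquant.segment_nuclei`).  Hybrid edge +
intensity rule on the red channel:

```
mask = fill(close(|Sobel| > k * RMS_gradient)) AND (I >= 0.7 * mean(top 1% of I))
```

The Sobel magnitude thresholded at `k` times the image's own RMS gradient
finds nucleus contours at any exposure level; morphological closing (disk,
radius 3 px) seals small gaps; hole filling produces solid blobs; the
intensity term removes edged-but-dim texture.  The "top 1%" is taken by
value: the cutoff is the 99th-percentile value and all ties are included.
Default `k = 2.0`: on ground-truthed phantoms the Dice coefficient against
the true nuclear mask is flat at ~0.99 for `k` up to about 3 and collapses
beyond, because at tumor-level nuclear density the nuclei themselves
dominate the RMS gradient and the adaptive threshold overtakes the nucleus
boundary gradient; `k = 2` sits in the middle of the stable plateau.  All
parameters are configurable and recorded in provenance.

**Patch scoring** (`ncquant`).  The binary mask is tiled from the origin
into non-overlapping small patches of 198×198 px — 250×250 µm at the
default pitch of 1.2626 µm/px, chosen so that those two figures are
consistent; N/C per patch is white pixels / patch pixels, with edge
patches scored over their true area and flagged partial.  Neighbouring 8×8
small patches are averaged (zeros included) into 2×2 mm large patches,
matching the ~2 mm sampling pitch of standard breast pathology.  A full
block is *excluded* when more than half — i.e. more than 32 — of its small
patches contain no cells at all (N/C = 0); a block with exactly 32 zeros
is kept.  Edge blocks are kept only if they contain at least 32 small
patches and satisfy the zero rule proportionally.  Large patches are
labelled by majority vote of a tissue-class raster over their footprint,
ties broken toward the globally rarer class and recorded.

**Classification** (`classify`).  The decision rule is "invasive iff
N/C ≥ t" (invasive carcinoma has the higher N/C).  The ROC curve sweeps t
over the observed values; the trapezoid AUC equals the tie-aware
pair-counting probability P(N/C_inv > N/C_norm) + ½P(tie), which the test
suite verifies against an O(n²) oracle to 1e-12.  The operating point is
the Youden index J = max(sens + spec − 1), ties broken toward the higher
threshold (fewer false positives).  Reader confusion matrices are
summarised as sensitivity/specificity/accuracy percentages, rounded
half-up to two decimals for reporting (full precision internally);
evaluators are averaged as the unweighted mean of their percentages.
Group differences between tissue subtypes are tested by a sample-level
cluster bootstrap (whole samples resampled with replacement within group,
≥1000 replicates, percentile CIs, two-sided bootstrap p-values,
Holm-adjusted across pairs).  This replaces a generalized-estimating-
equations fit with Tukey contrasts: both respect within-sample
correlation, and the resampling analogue is self-contained and
assumption-light; the output labels it as such.

## The phantom: what it emulates, and what it does not

Real MUSE data for this application are not publicly deposited, so the
`phantom` module generates ground-truthed stand-ins of the image
*phenotype*: PI-bright nuclei as filled ellipses in the red channel,
EY-green cytoplasm/stroma, adipocytes as dark rounded vacuoles with nuclei
confined to rims and septa, invasive tumor as dense enlarged nuclei, plus
a radial vignette (gain `1 − s·(r/r_max)²`, mean-normalised; centre/corner
ratio `1/(1−s)`) and additive Gaussian sensor noise on the 0..1 scale.
Nuclei are placed by a hard-core point process — Poisson count at the
class density, dart-throwing placement with minimum centre separation
0.8× the sum of radii — so the ground-truth nuclear fraction is well
defined and the target count is met except at saturation.

Default densities and radii were set once, by the identity
*fraction ≈ density × mean nucleus area*, to land the per-class nuclear
area fractions at realistic values: ~0.20 for IDC and ~0.23 for ILC
(enlarged 6 µm mean-radius nuclei at 1700 and 2000 /mm²), ~0.07 for
fibrous/glandular stroma (5 µm at 900 /mm²), ~0.03 for adipose-rich
tissue (350 /mm²), lobules/ducts intermediate at 1400 /mm².  Emission
intensities are free parameters (no quantitative stain statistics exist to
match); the defaults put nuclei in the top few percent of red-channel
intensities, the regime the 70%-of-top-1% rule presumes.  A smooth
multiplicative texture (σ = 1.2%) keeps tissue from being perfectly flat.

The phantom does **not** model optical point-spread, the ~20 µm DUV
penetration depth and its sub-surface occlusion effects, real chromatin
texture, nucleus overlap/clumping beyond the hard-core relaxation, or
autofluorescence.  Consequently the phantom classes are *cleanly*
separated: the pipeline's patch-level AUC on phantoms is essentially 1.0,
and passing the qualitative AUC > 0.8 check shows the chain preserves the
class contrast it is given — it does not certify the discrimination
achievable on real tissue, where reported performance is materially lower
(AUC ≈ 0.86).  The same caveat applies to the near-perfect Dice: real
nuclei are harder to segment than rendered ellipses.

## Numerical and design choices

- Internal image processing is floating point; outputs are re-quantised to
  the input bit depth (round-half-even via `rint`), so identity operations
  are bit-exact.
- Patch tiling and merge blocks are anchored at the mosaic origin
  (0-based, half-open windows).
- The brightest-pixel threshold uses 0.7 × the *mean* of the top-1% values
  (not 0.7 × the 99th-percentile value): the mean reading is stable under
  bright outliers; the threshold actually used is recorded in provenance.
- Histogram equalization leaves degenerate (single-valued) channels
  unchanged.
- Shading gains are floored at 1e-6 before mean-normalisation; fields are
  validated strictly positive with mean 1 ± 1e-6.
- Registration scores are computed on a centred crop of at most 192×192 px
  of the overlap — ample signal at a fraction of the cost.
- Bootstrap p-values use the (count + 1)/(B + 1) convention, so p is never
  exactly zero.

## Problem sizes

Desk-scale defaults keep every run small: scenes of ~1260×940 px
(≈1.6×1.2 mm) cut into 12 tiles of 760×600 px with the protocol overlaps
of 0.75/0.60 mm (594/475 px); property tests and the acceptance script
score 64-px small patches merged 4×4 (the same two-level construction at
1/3 scale, with the zero-limit scaled proportionally to 8) so that each
scene yields several large patches per tissue class.  A real acquisition
(2748×2200 px tiles, 198-px patches, 8×8 blocks, limit 32) is the default
configuration of the library itself; nothing in the code depends on the
desk scale.

## Known limitations

- The shading estimator assumes the illumination pattern is static across
  the tile stack and tissue is not; specimens with large empty areas can
  bias the median toward background.
- Segmentation is pixel-level only: no instance counting, no
  shape/pleomorphism features, and touching nuclei merge into one blob.
- The exclusion rule's proportional extension to partial edge blocks, the
  tie-break rules (higher Youden threshold, rarer tissue class) and the
  origin anchoring are package conventions; alternatives would shift
  results only at patch boundaries.
- `cluster_compare` is a stand-in for a full marginal regression model; it
  tests mean differences only, and its CIs are percentile-based.
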