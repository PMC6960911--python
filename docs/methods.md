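# Methods

`orchardseg` segments individual citrus tree crowns in nadir RGB frames
taken by a low-altitude agricultural UAV. The method is classical computer
vision: an illumination-compensation step in HSI space, two chromatic
region-extraction backends switched by an under-extraction rule, per-region
color/texture descriptors, and a linear SVM that confirms or rejects each
candidate region. This note records the model, its assumptions, the
parameter choices that matter, and what the synthetic test bed does and
does not establish.

## Color model

Images are float arrays in [0, 1]. The HSI model used throughout takes
`I = (R+G+B)/3`, `S = 1 − 3·min(R,G,B)/(R+G+B)` (0 for black pixels) and
the arccos hue reflected to `[π, 2π]` when `B > G`; hue is in `[0, 2π]`
and the band `[π/2, π]` is treated as vegetation green. The arithmetic-mean
intensity is chosen deliberately: the relative chromatic index below
divides by a brightness that must scale linearly with the RGB channels.

## Selective illumination compensation (SRIHE)

Orchard frames are often dominated by bright soil while crowns sit in
shadow. Global histogram equalization spends its dynamic range on the
background, so the intensity histogram is instead equalized only over the
green-hue pixel set `S_g = {p : π/2 ≤ H(p) ≤ π}`; hue, saturation and all
pixels outside `S_g` are untouched.

Two implementation choices differ from the most naive reading and are
load-bearing:

* **Transfer function.** The transfer is the probability integral
  transform using the *exact empirical CDF* of the masked intensities
  (`he_bins=None`). A quantized 256-bin transfer leaves a residual of a
  few gray levels between repeated applications whenever single histogram
  bins carry more than 1/256 of the mass (always true for the few thousand
  green pixels of a small frame); the rank-based transfer is exactly
  idempotent, because ranks map to ranks. An integer `he_bins` restores
  the classical quantized variant.
* **Gamut handling.** Raising `I` at fixed `(H, S)` can push the implied
  RGB outside [0, 1]. The inverse HSI transform is linear in `S` at fixed
  `(H, I)` — every channel is `I + S·f(H)` with the `f` summing to zero —
  so out-of-gamut pixels are brought back by shrinking their chroma with a
  single per-pixel scalar. This preserves hue and the equalized intensity
  exactly (a hard clip silently changes `I` and destroys idempotence);
  the fraction of adjusted pixels is logged. The cost is that strongly
  saturated bright pixels lose chroma, which is why the retinex backend
  below reads the original image (see *Pipeline order*).

Brightness condition: a scene is classed IB (insufficient brightness) when
the mean intensity over `S_g` is below 0.3, else SB; an image with no green
pixels defaults to SB with a warning.

## Chromatic extraction (ERGCM)

The relative green–red index `im = (G − R)/I` (0 where `I = 0`) is exactly
invariant to multiplicative illumination, unlike the plain `G − R`
difference. The extraction pipeline is: Otsu threshold on the index map
(keep pixels above), exclusion of components below 0.05 % of the image
area, morphological closing with a disk, and interior hole filling,
followed by 8-connected labeling. Otsu operates on a 256-bin histogram of
the min–max-scaled map and returns the bin edge maximizing between-class
variance (smallest edge on ties); a constant map raises a degenerate-
histogram error, which the pipeline converts to an empty region set plus a
warning.

## Under-extraction rule and retinex re-extraction (EMSRCM)

Weeds share the crowns' hue, so on weedy ground the chromatic threshold
merges crowns and weeds into few huge regions. The under-extraction
judgement rule flags a preliminary result when the foreground area ratio
exceeds `T_A = 45 %` or the region count falls below `T_N = 20`. Flagged
scenes are re-extracted:

1. multi-scale retinex reflectance `M_i = exp Σ_j W_j [log(S_i+ε) −
   log(S_i ⊗ G_j + ε)]` per channel, with equal weights, unit-sum Gaussian
   surrounds, reflect padding, and `ε = 1e−6` (single-channel form; the
   log-difference cancels any global illumination factor exactly as
   `ε → 0`);
2. the excess-green map `2G − R − B` of `M`;
3. grayscale closing → white top-hat → grayscale opening with disk
   structuring elements (decomposed footprints, so large radii stay fast);
4. Otsu binarization, one convex-hull pass per component, 0.05 % area
   exclusion.

The top-hat keeps bright structures narrower than its disk (crowns) while
flattening the broad weed field; the opening erases weed-scale bright
grains; the hulls repair crown edges eaten by the large-radius morphology.
Hulls of *overlapping* components merge, in which case the merged region is
no longer convex — iterating the hull to a fixpoint was evaluated and
rejected because overlapping hulls then cascade into scene-sized blobs on
heavily weeded scenes.

**Pipeline order.** The compensated image feeds the chromatic backend and
the feature extractor. The retinex backend reads the *original* image:
MSR is itself an exact multiplicative-illumination normalizer, so a second
brightness compensation is redundant, and the equalization's gamut
desaturation collapses the chroma of bright crown pixels — measured crown
recovery on weedy synthetic scenes was ~49 % from the compensated image
versus ~94 % from the original, identical under IB and SB illumination as
the MSR invariance predicts.

## Region descriptors (78 dimensions)

* **Color (14):** population mean and variance of R, G, B, H, S, a*, b*
  over the full region mask. Hue is an angle, so its statistics are
  circular (mean direction; variance `1 − |mean resultant|`). L and I are
  excluded by design — brightness is what the compensation already
  normalized. a*/b* come from the standard sRGB → XYZ(D65) → L*a*b*
  transform.
* **GLCM (5):** the region's texture window is quantized to 16 gray
  levels (uniform min–max bins); symmetric distance-1 co-occurrences are
  accumulated over 0°/45°/90°/135° and normalized to a probability matrix
  G. Statistics: contrast `Σ n² Σ_{|i−j|=n} G`, energy `Σ G²`, entropy
  `−Σ G·lg G` (base-10, `0·lg 0 := 0`), inverse difference moment
  `Σ G/(1+(i−j)²)`, and correlation `(Σ ij·G − u_i v_j)/(s_i s_j)` with
  the convention 0 when a marginal standard deviation vanishes.
* **Uniform LBP (59):** 8 neighbors on the radius-1 circle (bilinear
  sampling for the diagonals, ties count as ≥ center), computed for
  interior pixels. The 58 uniform patterns (≤ 2 circular bit transitions)
  occupy individual bins ordered by ascending 8-bit code; all non-uniform
  patterns pool into the last bin; the histogram is normalized to 1. The
  histogram is exactly invariant to positive affine gray transforms;
  under arbitrary monotone transforms invariance is exact only for the
  four on-grid neighbors, since bilinear interpolation does not commute
  with nonlinear maps.

The texture window is the region's maximum inner rectangle (largest
axis-aligned rectangle inside the mask, computed by the row-histogram /
monotone-stack method, ties to the top-left) at segmentation time, or the
full rectangle for training patches; the gray plane is the HSI intensity.
Regions whose window is smaller than 3×3 are logged and excluded.

## Classifier

A soft-margin linear SVM (C = 1, libsvm solver at tolerance 1e−8 so refits
and label-flip symmetry hold to ~1e−6) over z-scored features
(standardization fitted on the training set; zero-variance dimensions pass
through). A region is kept iff its signed decision score is strictly
positive. Training samples are cropped from illumination-compensated
synthetic scenes: every true crown is a positive (featurized exactly as at
test time), negatives are 12×12 rectangles inside the weed field and the
bare soil at a 4:1 weed:soil ratio, with half the weed rectangles drawn
from the highest excess-green weed areas so the negative class covers the
hard chromatic boundary. Models serialize to versioned JSON.

## Evaluation

Pixel metrics (IoU, precision, recall, F1, all in percent; two empty masks
count as perfect agreement) and tree-count metrics: predicted and true
regions are matched one-to-one greedily by descending IoU with a 0.5
acceptance threshold (configurable); CTR is matched true crowns over all
true crowns. ROC/AUC sweeps all score thresholds (trapezoid rule; equal to
the normalized Mann–Whitney U statistic).

## Synthetic orchard generator

No public dataset accompanies the method, so the package ships a
generator whose defaults are the study conditions for all tests:

* 200×200 px scenes at an implied ~0.18 m/px (a 2.8 m crown ≈ 16 px);
  30 crowns per frame of radius 7–11 px on a jittered planting grid
  (orchards are planted in rows) with a ≥ 6 px soil gap;
* crown boundaries carry low-order radial harmonics (±15 % of radius) —
  real canopies are lumpy, and perfectly elliptical crowns would make the
  convex-hull step lossless, hiding the edge-information cost of the
  retinex backend;
* crowns are dark saturated green with coarse multiplicative mottling
  (σ = 3 px, ±22 %); weeds are a yellower green with fine grain
  (σ = 0.7 px, ±20 %) in patches of scale σ = 9 px; soil is brown with
  gentle large-scale mottling; everything is blurred (σ = 0.6 px) and
  carries additive sensor noise (σ = 0.008);
* total green coverage (crowns + weeds) is driven to 0.25 / 0.47 / 0.70
  for the SWCR / MWCR / LWCR weed-coverage classes (class cutoffs 35 %
  and 60 % of green-hue pixels), and a global brightness factor of 1.0
  (SB) or 0.55 (IB) sets the brightness class around the 0.3 intensity
  cutoff;
* weeds keep a weed-free ring around each crown whose width reflects
  orchard-floor management: 7 px (≈ 1.2 m mowed strip) at low coverage,
  5 px at medium, 3 px at high — a 70 %-invaded orchard does not have a
  maintained strip, which is exactly why weeds encroach the crowns there
  and why the heavy-weed class is hardest.

All randomness flows through one seeded generator; scenes are bit-identical
given a seed, and per-scene seeds are spawned from a master seed. The
generator records ground truth (per-crown masks, weed mask) and the
brightness/weed-coverage classes recomputed from the rendered pixels.

What the generator does *not* emulate: perspective and terrain relief,
shadows cast by crowns, within-crown branch structure, sensor vignetting
and chromatic aberration, and the resolution of the real imagery (where
crowns span hundreds of pixels). Tests passing on these scenes show the
pipeline's logic and its qualitative behavior (backend switching,
illumination robustness, the precision/recall effect of the SVM stage);
they do not certify accuracy numbers on real orchard imagery.

## Scale mapping

The library defaults target full-resolution frames (ERGCM closing disk
5 px; EMSRCM closing 20 / top-hat 24 / opening 20 px; MSR surrounds
15/80/250 px). `PipelineConfig.for_synthetic_scenes()` scales the spatial
parameters to the generator's ~9 px crowns: ERGCM closing 3 px (seals
equalization-artifact bites at the crown-mottle scale while staying below
half the weed-free gap), EMSRCM closing 1 / top-hat 10 / opening 5 px
(top-hat at the typical crown radius; opening above the weed grain but
below the smallest crown), MSR surrounds (2, 10, 30) px. Problem sizes in
the test suite and the acceptance script (10 scenes per stratum, 200
training samples, 100×100 px scenes where many renders are needed) are the
package's chosen desk-scale study conditions.

## Numerical choices and degenerate inputs

* Otsu: 256 bins, smallest maximizing edge on ties; constant input is an
  error surfaced to callers, converted to an empty segmentation with a
  warning inside the pipelines.
* `im` and brightness classification treat `I = 0` pixels as 0 / exclude
  them via the hue convention (black pixels have hue 0, outside the green
  band).
* Boundary conventions: `I_A = 0.3` is SB; green-fraction 35 % is MWCR and
  60 % is LWCR; an SVM score of exactly 0 is background.
* Correlation and hue statistics have explicit zero-variance conventions
  (0 and circular variance 0 respectively); feature vectors are validated
  finite.
* Determinism: every stage is deterministic given inputs and config; the
  only randomness anywhere is the seeded generator and the recorded
  training seed.

## Known limitations

* Region-level classification is weak for small candidate regions: a
  false-positive weed hull of ~30 px yields a ≤ 6×6 texture window, too
  small for stable GLCM/LBP statistics, so the SVM's region ROC AUC on
  synthetic scenes (~0.66–0.74) is far below what the large regions of
  full-resolution imagery would support. The precision gain of the SVM
  stage is nevertheless systematic.
* Touching crowns are not split (no watershed); a merged pair costs both
  crowns under the one-to-one matcher.
* The under-extraction thresholds (`T_A = 45`, `T_N = 20`) assume a frame
  footprint holding a few dozen trees; they do not rescale with flight
  altitude.
* Uniform-LBP bin order is package-specific (ascending code value);
  histograms are not interchangeable with other libraries' uniform-LBP
  layouts without a permutation.
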