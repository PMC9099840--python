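# Methods

## Problem and approach

Cervicography grades acetic-acid-treated cervical images; the clinically
decisive boundary is between grade A1 (atypical, managed conservatively)
and P1B (dysplasia, requiring treatment). The visual criterion is the
acetowhite region: its opacity and border regularity track lesion
severity. This package implements and evaluates an image-level
recombination that privileges a rectangularly annotated acetowhite ROI:

1. build a *mask image* — original pixel intensities inside the annotated
   rectangle, exact black outside (the mask is not binary; its channels
   serve as intensity sources);
2. form a *superposition image* from one mask channel and two distinct
   original channels, placing each selected single-channel plane into the
   RGB slot of its own identity. Three mask-channel choices × three
   unordered original pairs give nine cases.

Because mask = original inside the ROI, an ROI pixel of a superposition
image carries three original channels while a background pixel carries
two (the mask slot is black there). Classification accuracy differences
between the original, mask and superposed variants therefore measure how
much concentrating channel capacity on the lesion helps.

## Slot assignment and naming

The composition is pure plane selection — no pixel arithmetic. Each
selected plane occupies the output slot of its channel identity. When the
mask channel coincides with one of the selected original channels (e.g.
MR together with OR), the mask plane keeps its native slot and the
displaced original plane takes the single remaining free slot; this is
the one deterministic convention consistent with the qualitative colour
descriptions of the recombined images (e.g. MR + OG + OB renders the
acetowhite purple-red and the background blue-green), and it is asserted
bit-exactly by the channel-conservation tests. Canonical case names put
the mask channel first ("MR + OB + OR"); the nine cases are enumerated
with mask channels in R, G, B order and original pairs in (G,B), (G,R),
(B,R) order.

## Preprocessing

Masking happens at native resolution, before any geometry change, so
annotation coordinates live in a single frame. The native 1504×1000
landscape frame is then cropped to a centred square (the lateral thirds
hold vaginal wall and speculum, not cervix): the square side is
min(width, height), the offset is the floor of half the discard, so an
odd discard loses the extra column (or row, for portrait input) on the
high-index side. Finally both rasters are bilinearly resized to 256×256
(bilinear is the conventional default and maps constant rasters to
themselves, which keeps mask zero-regions exactly zero until
interpolation at the ROI border). Rectangles are 0-based and half-open
throughout. The original and the mask go through identical crop/resize
geometry; `transform_roi` maps the annotation into the output frame
(clipping it to the crop window, returning None if it falls outside).

## Synthetic data

Clinical cervicograms are private, so the generator renders the gross
structure a practitioner would recognise: a pinkish elliptical cervix
disc with radial shading, a dark external os at the centre, lateral
speculum/vaginal-wall bands whose brightness varies image-to-image, and
one acetowhite patch inside the disc. Class-relevant structure is planted
*only inside the ROI*: the patch is blended toward white with opacity
0.35 for A1 (thin, translucent, feathered irregular border; fixed border
regularity 0.30) versus 0.65 for P1B (opaque, regular border, default
regularity 0.85). Everything else — patch placement and size,
illumination gain (lognormal-ish jitter, sd 0.08), clutter band width and
gain — varies with the seed but not with the label, acting as nuisance
variation. Additive Gaussian pixel noise has sd 8 (8-bit intensity
units). Channel means default to (R, G, B) = (185, 95, 135), matching the
R > B > G intensity-mass ordering seen on real cervigram histograms; the
parameter validator enforces that ordering and the A1 < P1B opacity
contrast. Per-image seeds derive from `SeedSequence([master_seed, index])`,
so datasets are bit-reproducible and images independent.

What the generator does **not** emulate: specular highlights, mucus,
blood, metaplasia look-alikes, camera vignetting, polygonal lesion
shapes, or any within-class severity spectrum. Passing tests therefore
demonstrate that the pipeline's machinery behaves as specified and that
the ROI-concentration mechanism helps *when the class signal truly lives
in the ROI*; they say nothing about absolute clinical performance.

## Classification harness

The dataset protocol is a stratified 8:2 train/test split and stratified
5-fold cross-validation (each image tested exactly once), both
seed-deterministic; with 438 + 477 images the split yields 382/95 for the
larger class. Folds are shared across image variants, so variant
comparisons are paired.

The default backbone is intentionally desk-scale, since the object under
study is the input representation, not the network: each 256×256×3 image
is reduced to an 8×8 grid of per-channel block means (192 features,
scaled to [0,1]), standardised, and classified by L2-regularised logistic
regression (C = 1, LBFGS). The pipeline is fully deterministic given the
data, trains in well under a second per fold on one CPU, and reaches 100%
training accuracy on separable inputs. Scores are positive-class
(P1B) probabilities; predicted label = P1B when the score reaches 0.5.
A ResNet50 transfer-learning backbone (ImageNet weights, Adam, batch 40,
200 epochs, learning rate 1e-4 — the conventional fine-tuning recipe for
this task) is available as `backbone="resnet50_transfer"` and raises a
clear error when torch/torchvision are not installed; it is consumed
off-the-shelf, never reimplemented.

## Evaluation and model comparison

Precision, recall, F1 and accuracy are computed from TP/FP/FN/TN counts
as percentages; zero-denominator metrics are defined as 0 with a warning
(rather than NaN or an exception) so fold averaging stays total. Fold
aggregation is the arithmetic mean of per-fold metrics — the aggregated
F1 is the mean of fold F1s, not the harmonic mean of the averaged
precision and recall. ROC curves sweep all score thresholds (ties grouped
into one step) and AUC is the trapezoidal area, which equals the
Mann–Whitney pair-ordering statistic; the test suite asserts that
identity to 1e-12.

Model comparison uses the Friedman rank test with models as treatments
and evaluation metrics as blocks: within each block, rank 1 is the best
(higher score better), ties receive average ranks, and
χ² = 12/(n·k·(k+1))·ΣR²ⱼ − 3n(k+1) is referred to the χ² distribution
with k−1 degrees of freedom. The χ² approximation (not an exact
small-sample table) is used deliberately: applied to the published
three-pipeline score table it reproduces the published p = 0.0388
(χ² = 6.5, rank sums 11/9/4). The default block set is the four
percentage metrics — the configuration that reproduces that printed
value — with AUC includable as a fifth block via an explicit argument or
the CLI flag `--include-auc`. The Nemenyi critical difference is
CD = q_α(k)·√(k(k+1)/(6n)) with q_α(k) the Studentized-range quantile at
infinite degrees of freedom divided by √2, evaluated at run time from
`scipy.stats.studentized_range` (so any α in (0,1) is accepted, not just
tabulated levels). The critical-difference diagram places models on a
rank axis, best (lowest mean rank) leftmost, and joins groups whose mean
ranks differ by less than CD.

## Numerical and degenerate-input choices

* Mask construction copies ROI pixels bit-exactly; the zero-set/copy-set
  partition is exact at native resolution (blending appears only after
  resizing, at the ROI border).
* Zero-area or out-of-bounds rectangles, single-class training sets,
  non-square resize inputs, mismatched original/mask dimensions, empty
  collections and malformed annotation lines all raise a validation error
  naming the offence; annotation parse errors cite the line number.
* `resize_to_target` short-circuits when the input already has the target
  size (bit-identical output).
* Scores are clipped into [0,1] after the head's predict_proba to guard
  against floating-point overshoot.

## Problem sizes

Unit tests run the generator mostly at 1/8 linear scale (188×125), which
preserves every geometric and statistical property under test. The
end-to-end demonstration and the acceptance script use 200 native-size
images (100 per class) under 5-fold CV across all eleven variants. At
this scale one fold misclassification moves accuracy by 2.5 percentage
points, so while the planted-signal ordering (best superposition ≥
original) holds at the demonstration's fixed seed and for most seeds, the
gap fluctuates within fold noise and can invert for individual seeds;
only the fixed-seed ordering is asserted.

## Known limitations

* Rectangular ROIs only; polygonal lesion masks are out of scope.
* The two-class opacity/regularity contrast is a deliberate abstraction;
  no claim is made about absolute clinical accuracy, only about the
  relative ordering mechanism.
* The pooled-logistic backbone has no spatial invariance beyond the 8×8
  pooling grid; it is a measurement instrument for input representations,
  not a clinical classifier.
* The Friedman blocks (evaluation metrics) are correlated, as they are in
  the published comparison this mirrors; the test's independence
  assumption is approximate in both.
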