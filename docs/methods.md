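# Methods

This note records the scientific and numerical choices behind the
package: the model, the post-processing algorithm, the evaluation
metrics, the synthetic-data generator that stands in for benchmark
data, and the known limits of what the tests demonstrate.

## Problem setting

Nucleus instance segmentation in single-channel (DNA-stain) fluorescence
microscopy: every pixel must receive both a foreground decision and an
object identity, so touching nuclei get distinct labels.  The framework
recasts the instance problem as 3-class semantic segmentation —
background / nucleus interior / nucleus boundary — followed by a seeded
region growing that converts the class probabilities back into
instances.  The boundary class is what makes clumped nuclei separable:
the interface between touching nuclei is boundary on both sides.

## Pre-processing

* **Normalization** maps the 0.1th/99.9th intensity percentiles to 0/1
  and clips.  Percentiles rather than min/max because fluorescence
  images routinely contain hot pixels; a single saturated pixel would
  otherwise compress the whole dynamic range.  Constant images map to
  zero.
* **3-class labels** are derived per instance: instance pixels whose
  Euclidean distance to the instance's complement is ≤ `boundary_width`
  (default 2 px) become boundary, the rest interior.  The *inner*
  boundary convention was chosen (boundary pixels belong to the
  instance) so that interior ∪ boundary exactly equals the binarized
  instance mask; this is one of several defensible readings and is
  isolated in `instance_to_three_class`.  Instances that erode away
  keep their innermost pixel (max distance-to-complement, ties to
  smallest row then column) as interior, so every nucleus can seed the
  post-processing.
* **Class weights** are inverse-frequency, mean-normalized:
  w_c = total / (3 · n_c).  Boundary pixels are rare (a ~2 px ring), so
  without weighting the loss is dominated by background.
* **Augmentation** draws uniformly from the rotation (multiples of 90°)
  × flip group.  Right-angle rotations avoid interpolating categorical
  labels.

## Network

ASW-Net is a "simplified W": three down-samplings and three
up-samplings arranged down–down–up–down–up–up, so the feature path
traces a W through scale space.  Channel widths are
`base_filters × {1, 2, 4}` across the three scales (the geometric
doubling convention of U-Net-family models; the reference figure prints
no channel counts).  Design points:

* conv blocks are two 3×3 convolutions, each followed by batch
  normalization (when enabled) and ReLU;
* down-sampling is 2×2 max pooling, up-sampling a 2×2 stride-2
  transposed convolution;
* the first decoding phase re-enters only the features computed before
  the second down-sampling — deliberately *not* the raw input, which at
  that depth would mostly re-inject noise;
* the original input is concatenated back in before the final 1×1
  classification layer, merging deep and shallow evidence;
* every skip in a decoding phase passes through an additive attention
  gate: skip and (nearest-neighbour-upsampled) gating signal are each
  projected by 1×1 convolutions to an intermediate width (half the skip
  width), summed, ReLU'd, projected to one channel and squashed by a
  sigmoid; the resulting coefficient map in (0, 1) multiplies the skip
  features.  The additive form is the established gate for
  segmentation; the coefficient maps are retained for visualization.

SW-Net is the identical graph with gates removed (plain skip
concatenation); the parameter difference between ASW and SW is exactly
the three gates.  A standard symmetric 3-scale U-Net (bottleneck
`8 × base_filters`) serves as the baseline.

The networks are implemented directly on numpy with a small
reverse-mode autodiff tape (`aswnet._autodiff`): im2col convolutions,
hand-derived backward passes for pooling, transposed convolution and
batch normalization, all verified against central finite differences in
`tests/test_autodiff.py`.  A `padding_mode="wrap"` option makes the
whole graph exactly equivariant to translations by multiples of 8,
which the test suite uses as a structural correctness check.
Weight init is Glorot-uniform from a seeded generator, so builds are
bit-reproducible.

Input sizes must be divisible by 8; the prediction path reflect-pads
arbitrary sizes (e.g. 520×696) to the next multiple and crops the
output back.

## Training

Weighted cross-entropy, normalized by the summed per-pixel weights
(not the pixel count) so the loss scale is comparable across class
balances; probabilities are clipped at 1e-7 before the log.  The
optimizer is RMSProp (ρ = 0.9, ε = 1e-7); its per-parameter adaptive
scaling is the "dynamic learning rate" — no external scheduler.
Early stopping halts after `patience_epochs` (default 10) consecutive
epochs in which validation loss fails to improve by more than 1e-6
(a strict-decrease threshold; plateaus at float-noise level should not
count as progress), and the best-validation weights are restored.

Defaults: learning rate 1e-3, batch size 4.  These are exposed
configuration, not claims; the single-image overfitting check uses
1e-2, appropriate for a 200-step run on one sample.

## Interior expansion

Seeds are 8-connected components of p_interior **strictly** greater
than 0.5.  Growth is synchronized (all seeds advance one pixel per
iteration, making the result independent of seed order):

* a frontier pixel p may claim an unassigned neighbour q only if
  background is not the dominant class at q, and either
  p_boundary(q) ≥ p_boundary(p) − 1e-6 (still climbing or on a plateau
  of the boundary ridge) or q is interior-dominant;
* once the candidate's boundary probability falls below the claiming
  pixel's, growth in that direction has passed the local maximum and
  stops;
* a pixel claimable by two different labels in the same iteration is a
  contested ridge pixel and stays unassigned permanently — this is
  what keeps clumped nuclei separated by a gap;
* when growth terminates, each label discards the pixels it claimed in
  its final iteration (the ridge top), leaving a one-pixel-wide
  unclaimed boundary;
* output = original seed pixels ∪ retained expansion pixels.

The ridge test is per claiming pair, so the "local maximum on the
expansion direction" is evaluated along each growth path rather than
globally.  The 1e-6 tolerance absorbs float noise on plateaus.
Termination is bounded by `max_iterations` (default: image diagonal).
Consequence worth knowing: even on a *perfect* probability map the
output is the true instance eroded by roughly one pixel (the discarded
ridge layer), so per-instance IoU against truth is ≈ (1 − P/A) for area
A and perimeter P — about 0.9 for a 20 px-radius nucleus.  That is the
algorithm's intended behaviour (thin, conservative boundaries), not an
implementation loss.  No minimum seed size is applied before expansion.

Ablation alternatives: marker-controlled watershed (markers = the same
seeds, elevation = p_boundary − p_interior, flooding restricted to
non-background-dominant pixels) and plain argmax thresholding
(components of the interior class).

## Metrics

All metrics are computed on the 0–1 scale (`--percent` rescales
reports by 100).  Definitions:

* **DICE1**: pixel Dice on binarized foregrounds.
* **DICE2**: object-level ensemble Dice — each truth object contributes
  its Dice terms against its maximal-overlap prediction and vice versa;
  objects with no overlap contribute their area to the denominator.
  Among the published ensemble-Dice variants this bidirectional form
  was chosen and is fixed here.
* **AJI**: aggregated Jaccard — truth objects in increasing label order
  greedily consume their best-IoU unused prediction (ties to the
  smaller prediction label, for determinism); unmatched areas inflate
  the union.
* **PQ = DQ × SQ** with the unique IoU > 0.5 matching;
  DQ = TP/(TP + FP/2 + FN/2), SQ = mean matched IoU.

Empty-vs-empty comparisons are defined as 1.0.  Dataset scores are
per-image metrics averaged unweighted (pooling across images is a
defensible alternative; per-image averaging matches common benchmark
practice).  The nucleus-area correlation (Pearson r over
mutual-maximal-overlap matched objects) quantifies downstream
morphometry agreement.  All four metric families are validated against
independent set-based brute-force oracles in the test suite.

## Synthetic data generator

The generator emulates the two regimes the method targets: clean,
fairly dense screens and low-SNR tissue images.  Model:

* nuclei are randomly oriented ellipses, semi-major axis drawn from
  `radius_range` (default 12–22 px — the scale of U2OS-type nuclei in
  520×696 screening images), axis ratio from `eccentricity_range`
  (default 1.0–1.8), boundary perturbed by Fourier modes 2–4 with
  amplitudes up to 8% (rounded-but-irregular outlines);
* intensity falls off radially (1 − 0.35ρ²) with ±20% per-nucleus
  brightness variation;
* a `clump_fraction` of nuclei (default 15%) is placed touching an
  existing neighbour; overlap pixels are ceded to the earlier nucleus,
  so clumped instances share a border but never pixels.  Non-clumped
  nuclei are rejection-placed pairwise non-touching;
* noise is additive Gaussian read noise of fixed SD (default 60
  intensity units on a background offset of 200), with optional Poisson
  shot noise; the signal amplitude is scaled so that mean in-nucleus
  signal / noise SD equals the target `snr` exactly before clipping.
  SNR 8 is the "clean" default; SNR ≈ 2 emulates the low-SNR regime.
* `density_mode` presets (low/medium/high ≙ 0.08/0.20/0.40 nuclei per
  1000 px²) mirror a density case study; the `bbbc039-like` preset
  produces the 100/50/50 split at 520×696.

Per-sample seeds derive from the master seed, split index and sample
index through `numpy.random.SeedSequence`, so datasets are
bit-reproducible.

What the generator does **not** emulate: border-clipped nuclei (all
nuclei are placed fully inside the frame), illumination gradients,
textured chromatin, mitotic figures, debris, and anisotropic PSF blur.
Passing tests therefore show algorithmic correctness and end-to-end
learnability under controlled conditions, not benchmark-level
performance on real microscope data — the latter requires the external
datasets and full-scale training (see README, "Reproducing the
results").

## Problem sizes used in tests and the acceptance script

The scaled experiment trains `base_filters=4` on a 40/10/10 split of
128×128 fields (six nuclei each, 15% clumped, SNR 8), ≤ 30 epochs,
batch 4 — a size chosen so the whole pipeline (generation, training,
prediction, scoring) completes in a few minutes on one CPU while still
exercising every stage.  The oracle sweep uses masks ≤ 32×32 with ≤ 5
objects, where brute force is exact and fast.  Interior-expansion
recovery uses 20 fields of 384×384 with 5–30 nuclei, 30% clumped.

## Known limitations

* The numpy implementation is CPU-bound and single-device; it is meant
  for correctness, small-scale experiments and teaching, not
  large-scale training.
* The middle-merge wiring of the W (which features the first decoding
  phase concatenates) follows the textual description; the exact
  per-block channel counts of the original figure are not recoverable,
  so alternatives are one-line swaps in the builder.
* DICE2 and the AJI tie-break have several published variants; the
  choices here are documented above and fixed by tests.
* Instances produced by interior expansion can occasionally touch where
  wobbly geometry makes a label's final geodesic claim layer differ
  from its full outer ring; contested ridges between seeds are always
  kept unassigned.
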