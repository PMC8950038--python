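# aswnet — nucleus instance segmentation for fluorescence microscopy

Accurate nucleus segmentation is the first step of most quantitative
cell-biology pipelines (morphometry, cell identification, protein
quantification), and it is hard exactly where it matters: noisy images
and clumped, touching nuclei.  `aswnet` implements a complete
instance-segmentation framework for single-channel (DNA-stain)
fluorescence images, built for researchers who need a lightweight,
fully inspectable tool:

1. **3-class semantic prediction.**  A per-pixel classifier assigns
   *background*, *nucleus interior* or *nucleus boundary*.  The
   predictor is **ASW-Net**, an attention-gated "simplified W"
   encoder–decoder: three 2× down-samplings and three up-samplings
   arranged down–down–up–down–up–up, with between-net concatenations,
   additive attention gates on every decoding skip, and the raw input
   concatenated back in before the 1×1 softmax head.  SW-Net (same
   graph, no gates) and a standard 3-scale U-Net are included for
   ablations.  The networks run on a small numpy autodiff engine —
   no GPU or deep-learning framework required — with gradients verified
   against finite differences.
2. **Interior expansion.**  Connected components of
   p_interior > 0.5 seed a synchronized region growing that climbs the
   boundary-probability ridge, leaves contested ridge pixels
   unassigned, and discards each seed's final claim layer — producing
   disjoint instances separated by one-pixel boundaries.  Watershed and
   plain thresholding are available as alternatives.
3. **Metrics.**  DICE1 (pixel Dice), DICE2 (object-level ensemble
   Dice), AJI (aggregated Jaccard), panoptic quality PQ = DQ × SQ, and
   nucleus-area Pearson correlation — all oracle-tested.
4. **Synthetic data.**  A seeded generator of fluorescence-like fields
   (wobbly elliptical nuclei, radial intensity falloff, controllable
   clumping and SNR) with exact ground truth, so the whole pipeline is
   testable end to end without downloading benchmark data.

Training uses weighted cross-entropy (inverse-frequency class weights),
RMSProp, rotation/flip augmentation, early stopping with a 10-epoch
patience and best-checkpoint restoration.  See `docs/methods.md` for
every modelling and numerical choice.

## Worked example

Score the interior-expansion algorithm on an ideal probability map
built from synthetic ground truth:

```python
import numpy as np
from aswnet import (SynthConfig, generate_nuclei_image, instance_to_three_class,
                    ProbMap, interior_expansion, threshold_labeling, evaluate)

# one synthetic field: 15 nuclei, 30% clumped, SNR 8
sample = generate_nuclei_image(SynthConfig(image_height=256, image_width=256,
                                           n_nuclei=15, clump_fraction=0.3,
                                           rng_seed=7))

# an ideal 3-class probability map built from the ground truth
label3 = instance_to_three_class(sample.truth, boundary_width=2)
probs = np.stack([(label3.classes == c).astype(np.float32) for c in range(3)])
prob_map = ProbMap(probs=probs)

report = evaluate(interior_expansion(prob_map), sample.truth)
print(f"interior expansion : AJI={report.aji:.3f}  DICE1={report.dice1:.3f}  "
      f"PQ={report.pq:.3f}  (TP={report.tp}, FP={report.fp}, FN={report.fn})")
baseline = evaluate(threshold_labeling(prob_map), sample.truth)
print(f"argmax thresholding: AJI={baseline.aji:.3f}  DICE1={baseline.dice1:.3f}  "
      f"PQ={baseline.pq:.3f}")
```

prints

```
interior expansion : AJI=0.922  DICE1=0.959  PQ=0.915  (TP=15, FP=0, FN=0)
argmax thresholding: AJI=0.763  DICE1=0.866  PQ=0.742
```

All 15 nuclei are detected (TP=15, no false positives or negatives);
the AJI of 0.92 rather than 1.0 reflects the deliberately discarded
one-pixel ridge layer at each nucleus boundary, and the gap to the
thresholding baseline (0.76) is the value added by interior expansion
on clumped fields.

## Command line

```bash
aswnet generate --preset bbbc039-like --out data/ --seed 1
aswnet train    --manifest data/manifest.tsv --variant asw --seed 1
aswnet predict  --checkpoint runs/default/best.npz --out pred/ \
                --postprocess interior_expansion data/test/image_*.tif
aswnet evaluate --pred pred/ --truth data/test/ --percent --out scores.csv
aswnet visualize --checkpoint runs/default/best.npz \
                 --image data/test/image_0000.tif --what attention --out viz/
```

Images and label maps are TIFF/PNG (labels: 16-bit TIFF, 32-bit when
labels exceed 65535); probability maps are 3-page float32 TIFFs
(background, interior, boundary).  Images whose dimensions are not
divisible by 8 — e.g. 520×696 — are reflect-padded for the forward pass
and cropped back.

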