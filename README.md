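# pixelcl

Pixel-level confident-learning label-noise detection and correction for
semantic segmentation masks, with a focus on retinal fundus annotations
(background / retina / fovea / vessel / optic disc, or two-class
vessel / background).

Manually annotated segmentation masks — even expert-made benchmark ground
truths — contain mislabeled pixels, concentrated at ambiguous structure
boundaries such as fine vessels. Training or evaluating a segmentation model
against such masks corrupts both the model and the benchmark. `pixelcl`
adapts confident learning (CL) to the pixel level: it uses a model's
per-pixel class probabilities as statistical evidence to find, rank and
optionally relabel suspect pixels, without retraining anything.

## The method

Given per-pixel class probabilities `p̂(ỹ = j; x)` and observed labels `ỹ`:

1. **Self-confidence thresholds.** For each class `j`,
   `t_j = mean{ p̂(ỹ = j; x) : x observed as j }` — the average confidence
   the model has in class `j` on pixels annotated as `j`.
2. **Confident joint.** For each pixel observed as `i`, the eligible classes
   are `{l : p̂_l ≥ t_l}`; the confidently inferred class `j` is the argmax
   of `p̂` over that set. `C[i][j]` counts pixels observed `i`, inferred `j`.
   Pixels with an empty eligible set are *out of distribution*: excluded
   from `C` and routed to human review.
3. **CJA (confident joint analysis).** Off-diagonal pixels of `C` are label
   issues; TP/FP/FN per class read directly off the matrix, and the
   relabeling policy replaces each flagged pixel's label with its inferred
   class.
4. **PBNR (prune by noise rate).** Each pixel gets a normalized margin
   `(p̂_ỹ − max_{l≠ỹ} p̂_l + 1) / 2`; pixels ranked ascending put the most
   suspicious labels first. The default refinement retains all pixels and
   uses the ranking to guide review; classic per-class-pair pruning is an
   explicit opt-in.
5. **Evaluation.** Global/class accuracy, IoU, frequency-weighted IoU and a
   boundary F1 score (BFScore within a pixel tolerance), plus a 2×2
   confusion comparing the detected issue mask against the authentic
   disagreements between two annotation sets; a noise-transition matrix
   `T[i][j] = P(ỹ=i | y*=j)` is estimated from such annotator pairs.

A synthetic module generates five-class retinal phantoms (FOV, optic disc,
fovea, branching vessel tree), injects class-conditional label noise from a
specified transition matrix, and simulates calibrated probability maps — so
the whole pipeline runs and is validated at desk scale with no downloads.

## Worked example

```python
import numpy as np
from pixelcl import (default_fixture, compute_thresholds, compute_confident_joint,
                     detect_label_issues_cja, refine_mask_cja, true_issue_mask,
                     evaluate_issue_detection, evaluate_segmentation)

fx = default_fixture(seed=42)            # 256x256 phantom, 5% label flips
truth, noisy, prob = fx["truth"], fx["noisy"], fx["probmap"]

t = compute_thresholds(prob, noisy)
joint, grid = compute_confident_joint(prob, noisy, t)
issues = detect_label_issues_cja(noisy, grid)
conf = evaluate_issue_detection(issues, true_issue_mask(noisy, truth))
print(issues.count, joint.excluded, round(conf.precision, 3), round(conf.recall, 3))

refined, _ = refine_mask_cja(noisy, grid)
for name, mask in [("noisy", noisy), ("refined", refined)]:
    rep = evaluate_segmentation(mask, truth, tolerance=2)
    print(name, round(rep.mean_iou, 4))
```

prints

```
2769 11089 0.998 0.836
noisy 0.6842
refined 0.9027
```

Of 65,536 pixels, 3,306 carry injected label errors (5% prevalence); CL
flags 2,769 pixels of which 99.8% are real errors (83.6% of all errors
found), 11,089 low-confidence pixels are set aside as out of distribution,
and relabeling the flagged pixels lifts the mean IoU against the true mask
from 0.684 to 0.903.

The same loop runs from the shell via the `pixelcl` CLI
(`simulate`, `thresholds`, `joint`, `detect`, `rank`, `refine`, `metrics`,
`issues-eval`), all subcommands sharing one YAML config.

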