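# Methods

## Model and assumptions

`pixelcl` treats each pixel of a segmentation mask as a noisily labeled
example. The noise model is class-conditional and position-free: the
probability that a pixel truly of class `y* = j` is annotated as `ỹ = i`
depends only on the class pair, collected in a column-stochastic transition
matrix `T[i][j] = P(ỹ = i | y* = j)`. Confident learning further assumes
access to a probabilistic classifier whose per-pixel class probabilities are
informative about the *true* class — i.e., a model that has generalized past
the label noise rather than memorized it. Under these assumptions the
self-confidence threshold

    t_j = mean over pixels observed as j of p̂(ỹ = j; x)

is pulled *down* by the mislabeled fraction of class `j` (their class-j
probability is near zero), which is exactly what lets genuinely mislabeled
pixels clear the threshold of their true class and land off-diagonal in the
confident joint

    C[i][j] = #{ x observed as i : p̂_j ≥ t_j and j = argmax over eligible l of p̂_l },

with eligibility `p̂_l ≥ t_l`. Pixels with an empty eligible set are out of
distribution (OOD): the model is confident about no class, so the framework
refuses to overrule the annotator and routes them to human review. The
conservation identity `sum(C) + excluded = pixels processed` holds on every
input and is asserted in the tests.

### Orientation

Internally `C[observed][inferred]`, following the definition's subscript
order. Published reports commonly print the transpose (rows labeled by the
inferred "true" class, columns by the observed class);
`ConfidentJoint.from_true_by_observed` / `to_true_by_observed` convert, and
CSV writers emit the printed layout. Report CSVs print class labels 1-based;
everything internal is 0-based, row-major, with the ranked tables'
"Observation Index" the row-major linear pixel index (the convention is not
universal; we fix row-major and document it here).

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| threshold mode | dataset | thresholds pooled over the whole calibration set (per-pixel weighting); a per-image mode exists behind a config flag |
| boundary tolerance | `ceil(0.0075 · image diagonal)` px | distance within which predicted and reference boundary pixels match in the BF score (11 px at 1024²); overridable |
| margin scope | all | rank every pixel, or only CJA-flagged pixels (`issues_only`) |
| phantom size | 256 px | side of the synthetic fundus phantom |
| flip rate | 0.05 | default class-conditional label-flip probability in fixtures |
| sharpness | 6.0 | logit scale of simulated probability maps (≈0.95–0.99 peak mass) |

Decisions where the design was genuinely open:

- **Ties.** Argmax ties in the confident assignment break toward the lowest
  class id (occurrences are logged); ranking ties break by ascending pixel
  index. Probabilities exactly equal to a threshold count as eligible (the
  defining inequality is ≥).
- **Undefined thresholds.** A class with no labeled pixels in the
  calibration set has no threshold; it is ineligible for assignment and a
  warning is emitted, rather than silently using 0 (which would make the
  class absorb every pixel) or 1.
- **OOD pixels are never auto-relabeled.** Both refinement paths preserve
  their original labels and emit them in the review report — the framework's
  evidence standard for overruling an annotation is a *confident* competing
  class, which OOD pixels by definition lack.
- **IoU.** The standard form `TP / (TP + FP + FN)` is used throughout.
- **Class accuracy** is recall against the reference (`TP_c / (TP_c + FN_c)`),
  macro-averaged; classes absent from both masks are skipped (logged), not
  scored 0/0.
- **Boundary definition.** A pixel is boundary for class `c` if it belongs
  to `c` and any 4-neighbor does not (the image border counts as outside).
  Precision/recall use Euclidean distance transforms; the BF score is their
  harmonic mean, symmetric under swapping prediction and reference. The
  dataset-level mean takes the per-image class-mean first, then averages
  over images.
- **Issue-detection confusion** does not force TP+FP+FN+TN to equal the full
  image area when an exclusion mask was applied upstream; it conserves
  whatever pixel set it is given.
- **PBNR default is rank-only.** The production path retains every pixel and
  uses the ascending-margin ranking to guide refinement; deletion-style
  per-pair pruning (`prune_topk`, relabeling exactly the off-diagonal count
  per ordered class pair) is provided for fidelity to the classic
  formulation but is opt-in.

## Synthetic fixtures: what they emulate, and what they don't

`generate_phantom` draws a circular field of view filled with retina, an
elliptical optic disc, a small foveal disk and a connected branching vessel
tree grown from the disc center by a seeded recursive random walk (vessels
steer away from the fovea; background outside the FOV renders at intensity
0). Default geometry puts the vessel fraction at 4–12% of the FOV —
realistic for fundus masks. `inject_noise` applies the class-conditional
transition i.i.d. per pixel, with optional boundary jitter (labels within a
band of class boundaries resampled from random neighbors) to emulate the
empirical concentration of annotation errors at ambiguous boundaries.
`simulate_probmap` produces `softmax(sharpness · onehot(belief) + N(0,1))`
probability vectors with the belief class equal to the *true* class (or a
draw from an explicit confusion matrix); conditioning on the true mask
encodes the generalize-past-the-noise regime CL assumes. A flag conditions
on the noisy mask instead to stress-test the failure mode where that
assumption breaks. All generators are bit-reproducible given (params, seed).

What passing the fixture contract does **not** show about real data: the
phantom has piecewise-constant regions, exactly class-conditional noise and
a classifier whose errors are independent Gaussian logit perturbations. Real
fundus annotations have spatially correlated errors, miscalibrated networks
and genuinely ambiguous pixels; the fixture validates the machinery
(counting, thresholds, ranking, conservation, recovery), not clinical
performance.

## Numerical choices and problem sizes

- Probability maps must sum to 1 per pixel within 1e−6 in memory; file
  loading renormalizes deviations up to 1e−4 (counted and logged) and
  rejects anything larger. The normalized margin is clamped to [0, 1] only
  against floating-point drift.
- Transition-matrix columns must sum to 1 within 1e−9; columns for absent
  reference classes are NaN (undefined) rather than zero-filled.
- Nearest-neighbor mask resizing maps each output pixel to the input cell
  containing its center — no interpolation, so no ids are ever invented.
- Test problem sizes are desk-scale by design: the default fixture is a
  256² phantom with 5% flips (3,306 injected errors); statistical recovery
  tests use ≥10⁵-pixel grids, where the ±0.02 recovery band sits at ≥3
  binomial standard errors for every class; the oracle-equivalence check
  runs 200 random ≤32² images against an independent double-loop counter.
  The whole suite runs in a few seconds on one CPU.

## Known limitations

- Fixed per-class thresholds misjudge pixels near decision boundaries: a
  pixel can be confidently predicted (e.g., 0.93 for its class) yet fall
  below its class threshold and be set aside as OOD. Adaptive/local
  thresholding and spatial-continuity constraints are deliberately out of
  scope.
- Only the confident joint is estimated, not the full latent joint
  distribution with calibration; no model training or fine-tuning is
  included.
- The boundary-pixel definition (4-connectivity, border-as-boundary) is one
  of several in circulation; BF scores are comparable within this package
  but not necessarily across tools.
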