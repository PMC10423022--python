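# Methods

This note documents the models and procedures `phdseg` implements, the
parameters that matter, the synthetic data the tests run on, and the design
decisions taken where the design was genuinely open.  Every number quoted
here is computed by the test suite or the acceptance script, not asserted
from memory.

## Perceptual Hausdorff distance (PHD)

**Model.** Two binary masks are reduced to 1-pixel skeletons and compared as
point-sets `X`, `Y` under the tolerance distance
`Ψ(x,y) = f+(d(x,y))` if `d(x,y) > τ`, else `f−(d(x,y))`, with Euclidean
pixel distance `d`.  The metric sums the two directed mean nearest-neighbour
terms:

    PHD(X, Y) = mean_x min_y Ψ(x,y) + mean_y min_x Ψ(x,y).

Averaging (a modified Hausdorff) rather than taking the maximum makes the
value reflect global structure instead of the single worst outlier; the gate
`τ` forgives small misalignments the way a human rater does.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| `tau` (evaluation) | 3 | px | tolerance giving the best agreement with human preference judgements |
| `tau` (training losses) | 2 | px | tighter tolerance performs best as a training signal |
| `f_plus` | identity | — | distance above tolerance counts at face value |
| `f_minus` | 0 | — | distance within tolerance is fully forgiven |

`f_plus`/`f_minus` are pluggable (any non-negative vectorized maps;
`f_plus` must be monotone).  With non-default pairs where `f_minus` can
exceed `f_plus` values beyond the gate, the KD-tree fast path (which gates
the nearest Euclidean neighbour) and the literal all-pairs minimum can
differ; the defaults, and any ReLU-like pair, are exact.  The brute-force
double loop is kept in the package as an independent oracle and the test
suite checks agreement to 1e-9 on random point-sets.

**Edge cases.** The metric is undefined on empty point-sets and raises a
typed error naming the empty side.  Callers own the policy: the training
losses substitute the image diagonal as a large finite penalty so an
all-background prediction at initialization cannot crash a run.

## Skeleton extraction

Classical two-sub-iteration Zhang–Suen thinning, applied until no pixel
changes, with the frame border treated as background.  Foreground is
8-connected throughout.  Properties the tests enforce: output ⊆ input,
idempotence, and preservation of the 8-connected component count on membrane
phantoms.  Two caveats worth knowing:

* Zhang–Suen deletes an isolated 2×2 block entirely (a known property of the
  parallel deletion rules).  Membrane networks never contain such components,
  but arbitrary speckle masks may.
* Re-thinning a dilated skeleton recovers it only up to quantization: within
  1.5 px for dilation radius 1, and within `r` px for radius `r ∈ {2, 3}` —
  the deviation concentrates where the dilated network stops being a simple
  band (junction blobs, near-parallel membranes closer than `2r`).  Measured
  over 60 phantom seeds the deviation never exceeded `r`.

Distance-transform medial axes were deliberately not used: on sparse thin
membranes they are less stable than iterative thinning.

**Differentiability.** Training needs gradients through binarize→thin, which
are zero almost everywhere.  The forward pass is the exact discrete pipeline
(so reported loss values equal the metric); the backward pass is a
straight-through scheme: each surviving predicted-skeleton pixel receives the
gradient of its own PHD contribution `+Ψ/|X|` (lowering the probability of a
badly placed pixel lowers the loss), and each ground-truth skeleton pixel
with a positive residual receives `−Ψ/|Y|` (raising probability near missing
structure lowers it).  This is a heuristic surrogate, not the derivative of
a relaxation; the training smoke test (strict loss decrease, overfit F1)
is the acceptance arbiter.

## Metric suite

Pixel metrics come from the confusion matrix with membrane = foreground.
HD/ASSD use exact nearest-neighbour distances (KD-tree).  Topology metrics:

* **Betti error** `|Δb0| + |Δb1|` on the thinned masks. `b0` is the
  8-connected component count; `b1` is computed by planar duality — the holes
  of an 8-connected foreground are exactly the bounded 4-connected background
  components of the padded frame.  This equals the cubical-complex Euler
  characteristic computation but is unambiguous at thick junctions, and is
  exact for arbitrary pixel sets, evaluated whole-image (a patch-sampled
  variant is a possible extension, not implemented).
* **clDice**: harmonic mean of topology precision (fraction of the
  prediction's skeleton inside the ground-truth mask) and topology
  sensitivity (the converse).
* **Region scores**: cells are the 4-connected components of the background
  (the standard duality to 8-connected membranes).  V-Rand and V-Info are
  the foreground-restricted F-scores (restricted to ground-truth cell
  pixels; predicted-membrane pixels within that set form one label-0
  segment).  ARI and VOI are computed on pixels that are cells in **both**
  masks, which keeps them symmetric in (pred, gt); a ground-truth-only
  restriction would not be.  Border thinning of ground-truth membranes
  before region extraction is off by default.

RVD is reported signed, with an absolute-value flag.  Every metric carries a
direction tag so the consistency harness can turn values into preferences.

## Consistency harness

Given trials (ground truth, prediction A, prediction B, vote counts), a
metric prefers the side with the better value (exact equality → tie).  The
default score is per-response: metric-preferred votes over all votes, ties
contributing half credit (alternatives: drop ties, or per-trial-majority
scoring).  Per-response is the default because it uses every subject's
response rather than collapsing 20 votes to one bit.

## Training losses and schedule

* `L_pixel` = soft Dice + weighted cross-entropy over the two classes, with
  the Dice sums pooled over classes and `w_c` the reciprocal training-set
  class frequency (membrane is rare, so it is up-weighted).  The log is
  clamped at machine epsilon.
* `L_phd` = PHD(prediction skeleton, ground-truth skeleton) in the global
  branch plus the mean over local patches (patches with an empty ground-truth
  skeleton are skipped; an empty *prediction* skeleton against non-empty
  ground truth costs the frame diagonal).  The mean (not sum) keeps the loss
  scale independent of the patch count.
* `L_sim` = PHD between the global skeleton and the union of patch skeletons
  translated into global coordinates.  Note per-patch thinning wiggles the
  skeleton near patch seams by a pixel or two relative to whole-frame
  thinning; the default training tolerance (τ=2) absorbs this, so exact
  crops of a prediction cost 0.
* Total: `L = L_pixel + λ1·L_phd + λ2·L_sim` with the coarse-to-fine
  schedule `λi(e) = 0` for `e < k` (warm-up, default `k = 5` epochs) then
  `min(cap, rate·(e − k + 1))`, defaults rate 0.1/epoch and cap 1.0.  The
  exact ramp shape was an open choice; linear with a configurable slope and
  cap is the simplest monotone schedule satisfying the warm-up contract.

## Two-branch pipeline

The global branch segments the full frame; the local branch segments N
same-size crops (default 2×2 tiling; N is a free choice) with the *same*
parameter set — one model object serves both scales, which is what makes
`L_sim` meaningful.  Patch outputs are stitched back (overlaps averaged;
non-overlapping grids reconstruct exactly) and fused with the global map by
pixel-wise averaging, then binarized at 0.5 (strict inequality, fixed so
results are bit-exact).  The pixel loss is averaged over the two branches by
default (a sum mode is available).

The backbone is a small u-shaped fully-convolutional network
(conv3×3 → avgpool → conv3×3 → nearest-upsample → skip-concat → conv3×3 →
1×1 head → softmax, ~3k parameters at the default width) implemented in
numpy with manual backprop and Adam (lr 0.02).  This keeps the whole
training loop deterministic and bit-reproducible under a fixed seed on any
CPU, which the tests rely on (the λ-caps-0 run must bit-match a pixel-only
run).  The width, learning rate, and steps per epoch (default 5 passes over
the training pairs) are configurable; the defaults are sized for the
desk-scale smoke test — one 64×64 phantom, 20 epochs, a few seconds — not
for real EM volumes.

Ablation switches mirror the natural design axes: `branches ∈ {global,
local, both}` and `use_phd` / `use_sim` on top of the always-on pixel loss.

## Synthetic phantoms

`generate_phantom` builds a Voronoi mosaic: `n_cells` random sites (minimum
separation `max(4, 3·thickness)` px, rejection-sampled deterministically), a
pixel joins the membrane when its nearest-site label differs from its right
or lower neighbour — giving a 1-px 8-connected boundary network whose
complement has exactly `n_cells` 4-connected cells — then dilation to the
requested thickness (disk of radius `(t−1)//2`; exact for odd `t`, even `t`
rounds down).  Defaults: 96×96 frame, 5 cells, thickness 3, chosen so a cell
spans a few tens of pixels as membrane mosaics do at moderate magnification
while keeping every test fast.

Perturbations: `dilate(r)` (thickness error), `shift(dr, dc)` (misalignment,
zero-filled at the frame), `delete_edges(fraction)` (remove whole skeleton
branches — curve segments between crossing-number ≥ 3 junctions — in random
order until the given fraction of membrane *length* is gone, then re-dilate),
`add_spurs(k)` (attach k short random branches).  Interpreting the deletion
fraction as membrane length rather than branch count guarantees the
perturbation is actually structural: a branch-count fraction can select only
tiny segments whose removal no metric (or human) would notice.

`make_trials` pairs a tolerated perturbation A (shift of Euclidean norm ≤ 3,
half the time plus a 1-px dilation) against structural damage B (20–40 % of
membrane length deleted) and simulates 20 observers voting for A
independently with reliability 0.9.  What passing the consistency tests
shows is therefore that PHD prefers within-tolerance misalignment to missing
structure on *clean, closed-cell binary mosaics* — it says nothing about
texture, staining artifacts, anisotropy, or ambiguous human judgements on
borderline structural errors, none of which the generator emulates.  The
grayscale renderer used by the training smoke test draws
ground-truth-correlated Gaussian intensities (membrane ≈ 0.85, background
≈ 0.15, σ = 0.05): enough contrast for a segmentation network to learn from,
with none of the hard texture of real EM.

Rare pathological trials exist by construction: when a 1-px dilation merges
the two membranes of a very narrow cell, the merged blob's medial axis can
sit far from the true skeleton and PHD scores the "tolerated" candidate
badly.  This occurred in 1 of 100 benchmark trials and is left in place; the
preference-direction test requires ≥ 95/100, not perfection.

## Numerical and degenerate-input choices

* Binarization threshold comparisons are strict (`> τ` for Ψ uses strict
  `>`; probability binarization uses strict `> threshold`), fixed so tests
  are bit-exact.
* Integer rasters are read as binary only when their values are a subset of
  {0, dtype-max} (or {0, 1}); two-valued mid-range rasters remain probability
  maps so quantized probability maps round-trip as probabilities.
* Coordinates are (row, col), 0-based, origin top-left, everywhere.
* All randomness flows through `numpy.random.default_rng(seed)`; no global
  state.

## Known limitations

* The PHD fast path assumes the tolerance pair is ReLU-like (see above).
* The straight-through structural gradient cannot *create* structure in
  regions the pixel loss has driven to confident background; warm-up ordering
  (pixel first) matters.
* The pipeline is desk-scale by design: single-channel 2-D images with even
  sides, one CPU, tiny backbone.  It demonstrates the loss machinery and the
  global–local architecture; it is not tuned for, or validated on, real EM
  benchmarks.
* Phantoms are binary and noise-free; consistency results on them bound what
  the metric does under ideal conditions only.
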