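# Methods

## Problem and model

Tumor budding is scored at the invasive front of a carcinoma, where
detached clusters of 1–4 tumor cells predict aggressive disease. Because
bud-level supervision is expensive and noisy, `budmil` treats detection as
weakly supervised multiple instance learning: the label lives on a 512×512
px region of interest (bag), not on its 96×96 px tiles (instances). Under
the standard MIL assumption a bag is positive iff at least one instance
contains a bud.

Each instance is embedded by a *frozen* encoder into h_k ∈ R^D. The
aggregator is gated attention pooling: two parallel linear maps V, U ∈
R^{L×D} produce a tanh-activated response and a sigmoid-activated gate,
their element-wise product is scored by w ∈ R^L, and a softmax over the K
instances yields attention weights a_k. The bag embedding z = Σ_k a_k h_k
feeds a linear head p = sigm(cᵀz + b), trained with bag-level binary
cross-entropy. The attention branch gives the model permutation
invariance over instances and an intrinsic localization signal.

Everything is implemented in numpy. The backward pass is derived by hand
(softmax Jacobian–vector product, gated tanh/sigmoid products, linear
head) and verified against central finite differences at 1e-4 relative
tolerance in the test-suite. The softmax subtracts the max logit; the BCE
probability is clamped to [1e-7, 1 − 1e-7], and the analytic gradient is
zeroed where the clamp saturates so it remains the true gradient of the
computed loss.

## Bag construction

A positive bag encloses each annotated bud: the ROI is centred on the bud
anchor (polygon annotations reduce to their centroid), with the origin
clamped so the ROI stays inside the slide. Instances form the full regular
grid with offsets 0, 32, …, 416, i.e. ((512 − 96)/32 + 1)² = 196 tiles.
Negative bags tessellate annotated non-tumor polygons on a grid aligned to
the polygon's bounding box; an ROI is kept only when fully contained in
the polygon, which guarantees negatives carry no tumor tissue at the cost
of discarding boundary area. Rectangles are half-open, so a point on an
instance's right/bottom edge belongs to the next tile. No blank-tile
filtering is applied by default (`min_tissue_fraction` exists but is off).

## Training protocol

Six folds; each fold is an **independent seeded random draw** of the unit
ids into train/validation/test at the stated sizes (the slide-level
protocol uses 10/10/9 of 29 slides). The alternative reading — one
systematic 6-way partition reused across folds — is not what we implement;
independent draws match "randomly selected in each fold". When the
sampling units are single bags rather than slides, an optional
label-stratified draw apportions each class proportionally across the
partitions, since an unstratified cut of a small bag set frequently lands
a single-class validation set (with slides as units the issue does not
arise, every slide containing bags of both classes).

Optimization is one Adam step per bag (lr 1e-4, β₁ 0.9, β₂ 0.999, weight
decay 1e-5 applied as L2 folded into the gradient, 30 epochs), with the
bag order reshuffled each epoch by a generator keyed on (seed, fold,
epoch). After every epoch the validation AUC is computed; the checkpoint
with the highest validation AUC is kept, ties resolving to the earliest
epoch (favouring the less-overfit model). AUC is the Mann–Whitney rank
statistic with average ranks (ties count ½); precision and recall are
reported at a configurable threshold, default 0.5. Fold metrics are
aggregated as mean with both sample SD and standard error, labelled
separately because "±" conventions differ across publications.

### Initialization

Attention parameters V, U, w are uniform in ±1/√fan-in with a required
explicit seed. The classifier head (c, b) is **zero-initialized**. With a
randomly initialized head the bag score starts as a random projection of
z, and at small learning rates the coherent learning signal (each Adam
step moves a coordinate by at most lr) cannot cancel that projection
within a short run — rankings stay essentially random. A neutral head
makes every bag start at p = 1/2, so the ranking that emerges is built
entirely from learned signal; zero-initializing a final layer is standard
practice and costs nothing at larger scales. There is no saddle: the head
gradient is non-zero at c = 0.

### Checkpoints for interpretation

Validation AUC on small validation sets saturates within a few epochs,
long before the attention branch finishes reorganizing; the best-val
checkpoint therefore often predates attention localization. All
classification metrics use the best-val checkpoint; attention analyses
(witness localization, heatmaps) read the final-epoch parameters exposed
as `FoldHistory.final_params`.

## Encoders

Foundation models (CTransPath, Phikon-v2, CHIEF, UNI) are registered with
their published metadata (backbone, parameter count, training paradigm)
and load through the `budmil.encoders` entry-point group; the package
never ships or downloads weights, and a missing plugin raises an
actionable error. Embedding dimensionality is taken from the loaded
plugin, not asserted. Tiles are fed at native resolution by default; a
`resize_to` hook exists for plugins whose training magnification differs.
The offline **toy encoder** is a handcrafted 32-dim feature map —
per-channel 8-bin histograms, means, variances (scaled by 4 so the [0,1]
bound is tight) and mean absolute horizontal/vertical gradients — chosen
to be deterministic, order-preserving and cheap; it is a real feature
extractor in its own right, adequate for pipeline and determinism tests,
not a stand-in for learned morphology features.

## Heatmaps and region scoring

Per-instance attention is rasterized by assigning every ROI pixel the mean
of a_k over the tiles covering it (up to 9 tiles at the default geometry;
`max` accumulation is available — mean was chosen for smoothness). For
display the map is min–max rescaled per ROI, constant maps mapping to
zero; the raw accumulation is retained for scoring. Agreement with bud
annotations thresholds the rescaled map (default 0.5), takes 8-connected
components, and counts: a bud annotation is TP when a single component
covers ≥ `min_overlap` (default 0.25) of its area, else FN; a component
touching no bud pixel is an FP. Point annotations are scored on a small
disc (default radius 8 px). This operationalization of heatmap agreement
is one defensible formalization of an inherently qualitative judgement;
note that FP *counts* are not monotone in the threshold in general
(raising the threshold can split one component into several), although the
detected pixel set itself shrinks monotonically.

## Synthetic data

Two generators make the package testable end to end with no downloads.

**Slides.** An H&E-like RGB image: eosin-pink background, darker
gland-like blobs in the tumor half, an invasive-front band in the middle
third, and planted buds of 1–4 small dark discs (the defining cluster-size
cap) at mutually separated positions inside the band, each annotated as a
point; non-tumor squares below the band are annotated as polygons. The
target is pipeline plausibility — correct geometry, labels and
determinism — not histological realism: there is no stain variation,
nuclear texture, inflammation or artifact, so passing pipeline tests says
nothing about recognizing real morphology.

**Embedding bags.** Negative instances are N(0, σ²I) with σ = 1; each
positive bag carries ⌈witness_rate·K⌉ ≥ 1 witness instances shifted by
δ·u along one fixed seeded unit direction u (single direction per
simulation so a linear head can succeed). Defaults: K = 16 instances of
dimension D = 8, 38 positive / 62 negative bags (the study's 3:5 class
ratio), δ = 2. The witness rate default is 0.35, calibrated as the
smallest value at which the generator's defining separability property —
a max-projection oracle onto u reaching AUC > 0.95 at δ = 2 — holds
robustly across seeds; it is also commensurate with the fraction of
stride-32 tiles that overlap a bud-sized object in a bud-centred ROI.
Witness masks are returned so attention localization can be scored
against ground truth.

At these desk-scale conditions the harness reaches mean six-fold test AUC
≳ 0.95 at δ = 2 and chance level at δ = 0, and trained attention ranks
witness instances above non-witnesses in ≥ 90% of positive test bags for
typical seeds. A known failure mode is the attend-to-negative-evidence
optimum — attention concentrating on *low*-signal instances with a
compensating head — which classifies almost as well but inverts
localization; it captures a minority of folds under some seeds.

## Problem sizes

Tests and the acceptance script run the six-fold protocol on 100 bags of
16×8 embeddings (60/20/20 per fold, 30 epochs), a 200-bag hold-out from
the same simulated world, and slide simulations up to 2048². These sizes
were chosen so the full study runs in seconds while keeping every
qualitative property of the larger protocol; the slide counts, bag counts
and embedding widths of a real foundation-model study are orders of
magnitude larger.

## Known limitations

- Real whole-slide pyramids (SVS multi-resolution access) are not read;
  slides are flat TIFF/PNG rasters at native resolution.
- No stain normalization or tissue masking; negatives rely entirely on
  annotation quality.
- The published cross-validation and hold-out numbers of the motivating
  study were obtained on private slides with external pretrained
  encoders; they cannot be recomputed here, and the synthetic study is a
  structural analog, not a reproduction.
- Binary presence/absence only: no bud counting, hotspot selection or
  severity grading.
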