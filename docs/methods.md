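# Methods

## Tracking model

The tracker assumes near-constant-velocity motion in image coordinates over
one-frame steps. State: $(u, v, \gamma, h)$ plus per-frame velocities, where
$u, v$ are the box-center coordinates (px), $\gamma = w/h$ the aspect ratio
and $h$ the box height (px). The observation model is linear (the first
four components). Process and measurement noise standard deviations scale
with $h$ — position terms as $h/20$ per frame, velocity terms as $h/160$ —
so uncertainty adapts to apparent object size without per-scene tuning;
aspect-ratio noise is a small constant ($10^{-2}$ process, $10^{-1}$
measurement). The measurement update uses the Joseph form, and covariances
are re-symmetrized after every step, so they remain symmetric positive
semidefinite under arbitrary predict/update sequences.

Association is a two-stage cascade per frame:

1. **Appearance stage.** Confirmed tracks, grouped by ascending
   `time_since_update`, bid for detections. Cost is the minimum cosine
   distance between the detection embedding and the track's gallery (up to
   `appearance_budget = 100` most recent embeddings). A pair is forbidden
   when its squared Mahalanobis distance in measurement space exceeds
   `gating_threshold` (the $\chi^2_4$ 0.95 quantile, 9.4877) or its
   appearance cost exceeds `max_appearance_distance = 0.2`. Each age group
   is solved by Hungarian assignment. Offering detections to recently
   updated tracks first means a bird occluded for a few frames cannot steal
   a detection from one tracked continuously — the main defense against
   identity switches.
2. **IoU stage.** Tentative tracks and confirmed tracks that missed the
   cascade but matched in the previous frame are offered the leftover
   detections at IoU cost, capped at `iou_fallback_threshold = 0.7`. When a
   detection or track lacks appearance information, the appearance cost
   itself falls back to IoU cost (logged at debug level).

Lifecycle: a spawned track is tentative; `n_init = 3` consecutive matches
(counting the spawning detection) confirm it at its third frame; a tentative
miss deletes it immediately; a confirmed track is deleted once
`time_since_update > a_max = 30` frames (at 25 fps, 1.2 s without a match
means the bird has left). Output rows are emitted only for confirmed tracks
matched in the current frame, and the reported box is the matched
detection's box: the filter state is the association machinery's estimate,
but the detection itself is the best available localization, and coasting
(unmatched) predictions would otherwise leak model drift into downstream
counting. The track's species label is the mode of its matched detections'
classes, most-recent class on ties, because a handful of misclassified
frames should not flip a long track's species.

## Counting

`make_board(h, w, coverage)` zeroes a centered rectangle of side
`round(dim * sqrt(coverage))` per axis inside an all-ones matrix, so the
zeroed fraction equals `coverage` (default 0.95) up to one-cell
quantization. A track is "in the counting area" when writing its box
footprint back onto the board puts a 1 inside the region — implemented as
the cell-rectangle intersection, which is exactly equivalent and avoids
copying the grid per box (a `render_marked` helper materializes the marked
grid for debugging). An alternative `mode="center"` counts only the
box-center cell; the full-footprint mode is the default because a bird
partially inside the region is visibly present in it. First-seen
(species, ID) pairs increment that species' count; seen-ID sets are global
for a run, so a bird that re-enters under a persisting ID is not recounted,
while a re-entry under a fresh ID counts again — inherent to ID-based
counting. Counts are cumulative, reported at checkpoint frames; checkpoints
past the end of the stream return final counts with a warning.

## Loss family, attention operator, augmentations

- `alpha_loss` defaults to $\alpha = 3$, the value the power-loss literature
  recommends; $\alpha = 1$ reduces exactly to classic IoU/GIoU/DIoU (tested
  against independent straight-line implementations to $10^{-12}$).
  Zero-area boxes take IoU 0, and penalty terms with vanishing denominators
  are defined as 0, so every loss value is finite.
- The attention operator uses reduction ratio $r = 4$, ReLU between the two
  MLP/convolution layers and 7×7 spatial kernels by default (all
  configurable). Random initialization is uniform in
  $\pm 1/\sqrt{\text{fan-in}}$ under an explicit seed. With all-zero
  weights both gates are exactly $\sigma(0) = 0.5$, giving the closed form
  output $= 0.25 \times$ input used as a test anchor.
- Mosaic scales each of four samples (aspect-preserving, covering its
  quadrant of the canvas split at the center point), maps labels through
  the same affine, clips to the canvas and drops boxes below
  $\max(4\,\text{px}^2, 10\%$ of the scaled box area$)$. Mixup blends
  pixels and label weights with $\lambda$ (typically drawn from
  Beta(8, 8)). HSV jitter multiplies each channel by $1 + u \cdot
  \text{gain}$, $u \sim U(-1, 1)$, with gains (0.015, 0.7, 0.4); hue wraps
  on its circle, saturation and value clip. When composed, the order is
  mosaic → mixup → HSV. All three are deterministic under a seed.

## Evaluation metrics

Matching is greedy in descending confidence within each (image, class)
group, each ground truth claimable once, ties in confidence resolved by
stable input order. AP integrates the precision envelope over recall
(all-point interpolation over the full curve rather than a fixed 11-point
grid — the modern convention, and exactly integrable). A class with no
ground truth has no defined AP and is excluded from mAP; mAP@0.5:0.95
averages over IoU thresholds 0.50–0.95 in steps of 0.05. TN — and therefore
accuracy — is only meaningful for closed classification tables; open-image
detection has no counted negative class, so the detection report omits it.

## The scene simulator

The simulator emulates what matters to tracking and counting: multiple
species, staggered entries and exits through image borders, smooth
individual motion, size diversity, and detector corruption. Defaults define
the counting-verification scene: 640×640 px, 25 fps, 60 s, 10 species, 60
birds entering over the first 70% of the run, boxes 20–60 px, speeds
1.5–4 px/frame with acceleration noise σ = 0.05 px/frame², appearance
embeddings of dimension 16 with per-identity unit-norm means and Gaussian
perturbation σ = 0.05 (renormalized), and all detector noise off. Birds
enter on the central 60% of a border heading within 45° of the inward
normal, so every bird genuinely transits the view. Detector corruption,
when enabled: independent misses (`miss_rate`), Gaussian box jitter
(`jitter_sigma`, px), and Poisson false positives per frame with uniform
random boxes and uniform-sphere embeddings (which appearance association
can reject). A "swerve" motion mode with a sinusoidally rotating heading
deliberately violates the tracker's constant-velocity assumption for
stress tests.

What the simulator does **not** model: occlusion (beyond independent
misses), correlated detector failures, lighting or background structure,
appearance drift with pose, camera motion, or birds landing and staying.
Passing tests on these scenes therefore demonstrate the correctness of the
association, lifecycle and counting logic under the stated assumptions —
not field-ready accuracy on real video, which depends on the detector and
embedding extractor supplied by the user.

## Known limitations and observed failure modes

- Ground truth counts a bird the instant its box touches the counting
  region; the pipeline can count it only once confirmed (frame 3 of its
  track). A bird whose region entry straddles a checkpoint by less than the
  confirmation lag shifts one cell's count to the next checkpoint.
- If a bird exits and another of the same species enters at nearly the same
  place within the deletion window, the IoU fallback stage can hand the
  coasting track over, merging two birds into one count. This is inherent
  to ID-based counting with appearance-blind fallback association; on the
  default scene it occurs in roughly one seed in ten and costs one bird.
- The Mahalanobis gate assumes the motion model; in "swerve" mode fast
  heading changes can momentarily throw detections out of the gate, relying
  on the IoU stage to recover.
- Hungarian assignment treats +inf as forbidden by padding with a large
  finite cost and filtering afterwards; among maximum-cardinality feasible
  matchings it returns a minimum-cost one.
- The counting-verification experiment uses the default scene sizes above
  (1500 frames, 60 birds), which exercise confirmation, deletion, crossings
  and region entry while keeping a full run in seconds.
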