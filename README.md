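# birdtrack

Automated monitoring of wetland birds needs three things after a detector
has done its work: linking per-frame detections into stable identities,
deciding when an identity should be counted, and keeping the tally per
species. `birdtrack` implements that post-detection stack — a
tracking-by-detection engine, a counting-board area counter, and the
detector-side building blocks (power IoU losses, a global attention
operator, mosaic/mixup/HSV augmentation, and the standard evaluation
metrics) — as a detector-agnostic Python library and CLI. A built-in scene
simulator generates multi-species flocks with ground truth, so the whole
pipeline can be exercised and validated without any video data.

It is aimed at ecologists and computer-vision practitioners who already have
(or plan to train) a bird detector and need the tracking/counting machinery
around it, plus reproducible synthetic benchmarks for it.

## The methods

**Tracking by detection.** Each track carries an 8-D constant-velocity
Kalman state $(u, v, \gamma, h, \dot u, \dot v, \dot\gamma, \dot h)$ — box
center, aspect ratio $w/h$, height, and their per-frame velocities —
observed through $(u, v, \gamma, h)$. Detections are associated to tracks by
a matching cascade: confirmed tracks, in ascending order of frames since
their last match, bid for detections with the minimum cosine distance to
their appearance-embedding gallery, subject to a $\chi^2_4$ Mahalanobis gate
on the predicted measurement; leftovers are matched by IoU. Hungarian
assignment resolves each stage. A new track is *tentative* until it matches
`n_init = 3` consecutive frames, then *confirmed*; a confirmed track is
*deleted* after `a_max = 30` consecutive misses. Track species is the
running mode of its matched detection classes.

**Counting board.** A 0/1 matrix the size of the image starts as all 1 with
a centered counting region zeroed; the region covers 95% of the image
(side scale $\sqrt{0.95}$ per axis). Per frame, each confirmed track's box
footprint is written back as 1s; if that puts a 1 inside the region and the
(species, track ID) pair is new, that species' count increments. Counts are
cumulative and reported at checkpoint times (15 s intervals by default).

**Power IoU losses.** The classic IoU/GIoU/DIoU regression losses
generalized by an exponent $\alpha$ (default 3):

$$L_{\alpha\text{-IoU}} = 1 - \mathrm{IoU}^\alpha,\qquad
L_{\alpha\text{-GIoU}} = 1 - \mathrm{IoU}^\alpha +
\Big(\tfrac{|C\setminus(A\cup B)|}{|C|}\Big)^{\!\alpha},\qquad
L_{\alpha\text{-DIoU}} = 1 - \mathrm{IoU}^\alpha +
\Big(\tfrac{\rho^2}{c^2}\Big)^{\!\alpha}$$

with $C$ the smallest enclosing box, $\rho$ the center distance and $c$ the
enclosing-box diagonal. $\alpha = 1$ recovers the classic losses exactly.

**Global attention operator.** $F_2 = M_C(F_1)\otimes F_1$,
$F_3 = M_S(F_2)\otimes F_2$: a per-location channel MLP gate followed by a
two-convolution spatial gate, both sigmoid-squashed, no pooling anywhere.
In a detection network this operator sits on the head side, in front of each
detection scale; this package ships the pure operator (training is out of
scope).

**Metrics.** Precision, recall, $F_1 = 2TP/(2TP+FP+FN)$, accuracy,
IoU-thresholded greedy matching, per-class AP as the area under the
precision envelope versus recall, mAP@0.5 and mAP@0.5:0.95.

## Worked example

```python
from birdtrack import (ScenarioConfig, simulate, Tracker, TrackerConfig,
                       run_counting, make_board, species_entry_counts)

cfg = ScenarioConfig(seed=0)          # 640x640, 25 fps, 60 s, 10 species,
gt, dets = simulate(cfg)              # 60 birds, noise-free detections
rows = Tracker(TrackerConfig()).run(dets)
checkpoints = [375, 750, 1125, 1500]  # 15, 30, 45, 60 s
counts = run_counting(rows, (640, 640), checkpoints)
truth = species_entry_counts(gt, make_board(640, 640, 0.95).region_box(),
                             checkpoints)
print(counts[750])
print(truth[750])
```

prints

```
{0: 6, 1: 7, 2: 3, 3: 4, 4: 4, 5: 7, 6: 3, 7: 2, 8: 6, 9: 5}
{0: 6, 1: 7, 2: 3, 3: 4, 4: 4, 5: 7, 6: 3, 7: 2, 8: 6, 9: 5}
```

— the pipeline's cumulative count per species after 30 s (47 birds total)
agrees with the simulator's ground truth in every cell; by 60 s all 60 birds
have been counted, with 60 distinct track IDs and no identity switches.
(`run_counting` also emits a `UserWarning` here because the last bird exits
at 57.4 s, so the 60 s checkpoint falls after the final confirmed-track row
and reports the final counts.) The
same flow is available from the shell:

```sh
birdtrack simulate --seed 0 --out-dir run/
birdtrack track    --detections run/det.csv --embeddings run/embeddings.npz --out-dir run/
birdtrack count    --tracks run/tracks.csv --out-dir run/
```

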