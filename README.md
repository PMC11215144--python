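# earcount

Counting wheat ears in UAV video by tracking-by-detection.

A drone flying a constant-speed pass over a wheat canopy produces a video
in which every ear drifts through the frame at the sweep speed. Given
per-frame ear detections (from any detector — this package deliberately
treats the detector as a pluggable input), `earcount` links them into
identities with a constant-velocity Kalman filter and Hungarian IoU
matching, and counts each identity exactly once when its center crosses a
fixed baseline near the bottom of the frame. The same machinery is useful
for any small-object counting task over a linear camera sweep; the
defaults are parameterised for wheat phenotyping (field counts in the
hundreds per pass, ears tens of pixels in size).

The package provides, as independently testable pieces:

- **geometry** — boxes, IoU, and the Normalized Gaussian Wasserstein
  Distance: a box `R = (cx, cy, w, h)` is modelled as the Gaussian
  `N(μ, Σ)` with `μ = (cx, cy)`, `Σ = diag(w²/4, h²/4)`; for two boxes the
  squared 2-Wasserstein distance has the closed form
  `W₂² = ‖μ₁−μ₂‖² + ((w₁−w₂)/2)² + ((h₁−h₂)/2)²`, and
  `NWD = exp(−W₂/C)` is a bounded similarity that, unlike IoU, still
  discriminates between disjoint box pairs — the basis of the NWD loss
  `L = 1 − NWD` for tiny-object detection.
- **spd** — the space-to-depth rearrangement (the lossless core of
  SPDConv): spatial `s×s` blocks move into channels,
  `(S, S, C) → (S/s, S/s, C·s²)`, with its exact inverse.
- **kalman** — an 8-state constant-velocity filter over
  `(cx, cy, w, h)` and their per-frame velocities:
  predict `x⁻ = F x`, `P⁻ = F P Fᵀ + Q`; update with gain
  `K = P⁻Hᵀ(HP⁻Hᵀ+R)⁻¹`.
- **assignment** — optimal one-to-one matching of predicted boxes to
  detections (Hungarian algorithm on the IoU matrix) with a 0.7 gate.
- **counter** — the per-frame loop: detect → match → count on baseline
  crossing → create/delete tracks.
- **metrics** — Pascal-VOC detection scores (P, R, F1, AP as the area
  under the precision–recall curve) and counting agreement
  `R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(ȳ−yᵢ)²`, `RMSE = √(Σ(ŷᵢ−yᵢ)²/n)`.
- **simulate** — a ground-truthed scene generator: a planar strip of
  static objects swept by a constant-velocity camera (default geometry: a
  5× downscale of a 3840×2160 @ 30 FPS pass at 0.5 m/s), plus a noisy
  detector channel (misses, localisation jitter, false positives, wind
  sway).
- **io / cli** — MOT-style CSV and LabelMe JSON readers/writers and the
  `earcount` command with `simulate | count | eval-detect | eval-count`.

## Worked example

```python
from earcount import (SceneConfig, CounterConfig, generate_scene,
                      corrupt_detections, run)

scene = SceneConfig(n_objects=120, n_frames=150, seed=42,
                    detect_prob=0.9, jitter_sigma=1.0)
truth = generate_scene(scene)
detections = corrupt_detections(truth)          # noisy detector channel
result = run(detections, CounterConfig(frame_size=scene.frame_size,
                                       baseline_y=truth.baseline_y))
print(f"true crossings : {truth.expected_count}")
print(f"counted        : {result.total}")
print(f"track identities created: {len(result.tracks)}")
```

prints

```
true crossings : 78
counted        : 78
track identities created: 309
```

78 of the 120 objects cross the counting baseline during the 150-frame
sweep (the rest lie beyond the swept window or below the line from the
start); despite 10% detector misses and 1 px jitter the counter recovers
all 78, counting each identity exactly once. More identities (309) than
objects exist because noise occasionally breaks a track — the baseline
rule is what keeps broken tracks from inflating the count: an identity
born below the line can never be counted.

The same flow from the shell:

```
earcount simulate --seed 42 --n-objects 120 --n-frames 150 \
    --detect-prob 0.9 --jitter-sigma 1.0 \
    --out-truth truth.csv --out-dets dets.csv
earcount count --detections dets.csv --out result.json
earcount eval-detect --pred dets.csv --truth truth.csv --iou 0.5
```

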