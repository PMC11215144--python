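# Methods

## Problem setting

A UAV flies a straight, constant-speed pass over a planar crop canopy
with a nadir camera. Every object (wheat ear) is effectively static in
the world, so in image coordinates all objects share one velocity — the
negated camera motion — and drift from the top of the frame to the
bottom. Counting is done by tracking-by-detection: an external detector
proposes boxes per frame, a tracker links them into identities, and an
identity is counted once when its estimated center crosses a fixed
horizontal baseline near the bottom of the frame. The line rule exists
for two reasons: boxes at the frame edges are unreliable (partially
visible objects), and identity switches must not produce double counts —
an identity can only be counted at the line, once.

## Box similarity: IoU and NWD

Boxes are axis-aligned, center form `(cx, cy, w, h)`, continuous pixel
coordinates, origin top-left, y downward. A box maps to the Gaussian
`N((cx, cy), diag(w²/4, h²/4))`; for two such Gaussians the squared
2-Wasserstein distance reduces to

    W₂² = (cx₁−cx₂)² + (cy₁−cy₂)² + ((w₁−w₂)/2)² + ((h₁−h₂)/2)².

The implementation uses this closed form; the general matrix form
`‖m₁−m₂‖² + Tr(Σ₁+Σ₂−2(Σ₂^½Σ₁Σ₂^½)^½)` (via `scipy.linalg.sqrtm`) is kept
as an independent route and the two are required to agree to 1e−9 in the
tests. The similarity is `NWD = exp(−d/C)`.

Two deliberate choices:

- **Exponent.** `NWDParams.use_sqrt` selects whether `d` is the distance
  `W₂` (default) or its square `W₂²`. The unsquared distance keeps the
  exponent unit-consistent (pixels over pixels) and matches the original
  NWD formulation; the squared variant is selectable because both appear
  in the literature.
- **C** (default 12.8 px) is a dataset-scale constant. It must be on the
  order of a typical object extent: much smaller and all non-identical
  pairs saturate near 0, much larger and everything saturates near 1. At
  the simulator scale objects are 6–20 px, so 12.8 px sits mid-range.
  There is no universally correct value; it is configurable.

Degenerate (zero-area) boxes are rejected with an error rather than
clamped — they always indicate an upstream bug. Note one floating-point
fact: for box pairs hundreds of pixels apart, `NWD < 1e−16` and the loss
`1 − NWD` saturates to exactly 1.0 in double precision, although it is
strictly below 1 in exact arithmetic.

## Space-to-depth

`space_to_depth` moves each `s×s` spatial block into channels,
`(S_r, S_c, C) → (S_r/s, S_c/s, C·s²)`. It is a pure index permutation —
no arithmetic — which is the property that makes it attractive for small
objects: downsampling without information loss. Sub-maps
`f[i,j] = x[i::s, j::s]` are concatenated with the row offset varying
fastest (`[f00, f10, f01, f11]` at `s = 2`); the stacking order is a free
convention (all invariants are order-independent) and is documented
rather than configurable-by-default. The learned 1×1 convolution that
follows the rearrangement in SPDConv is out of scope; a fixed linear
`mix` matrix argument marks where it would sit. `depth_to_space` is the
exact inverse, and the round trip is property-tested for scales 2–4.

## Kalman filter

State: `(cx, cy, w, h, vcx, vcy, vw, vh)` — box center, size, and their
per-frame velocities. With dt = 1 frame, `F = [[I₄, I₄],[0, I₄]]`,
`H = [I₄ | 0]`. Covariance propagation is `F P Fᵀ + Q` (the transpose is
required for `P` to remain a covariance). The control term `B u` exists
in the API but defaults to absent: passive objects have no control
input. Observation noise enters through the covariance `R`, not as a
sampled disturbance.

Defaults (all configurable, units px and frames):

| parameter | default | rationale |
|---|---|---|
| Q positions/sizes | 1e−2 | objects are static in the world; only sway and model error remain |
| Q velocities | 1e−4 | the sweep speed is constant; velocity should barely random-walk |
| R | 1 px² | detector localisation error of order 1 px at simulator scale |
| init P positions | 10 | a detection localises the object to a few px |
| init P velocities | 1000 | velocity is unobserved at birth; the prior must not fight the first innovations |

The posterior covariance is symmetrised after every update; the suite
checks it stays PSD over 1000 random cycles, and that the whole filter
tracks an independent plain-matrix implementation to 1e−10. Predicted
states with `w ≤ 0` or `h ≤ 0` are flagged (`state_box` returns None) and
the track sits out matching that frame rather than being clamped.

## Matching

Per frame, the pairwise IoU matrix between Kalman-predicted boxes and
detections is solved as a linear assignment problem maximising total IoU
(`scipy.optimize.linear_sum_assignment`); assigned pairs that do not
exceed the gate are then dissolved. Gating after the global solve is the
default (`pre_mask=True` masks first instead; both orders are defensible
and the difference is rarely visible). The gate is strict: a pair must
exceed 0.7, not reach it. An NWD-scored matching mode exists behind a
flag for experimentation with very small objects.

## Counter design

Each `Tracker.step` runs: predict all tracks → match → update matched
tracks and test the baseline crossing → spawn tracks from unassigned
detections → delete tracks unmatched for more than `max_age` frames.
IDs are a global monotone counter from 1, never reused. The crossing test
compares the track's posterior center y at its previous matched frame
with the current posterior y: a downward crossing of `baseline_y`
(default 90% of frame height) counts the track, at most once. A track
coasting on prediction alone can never be counted — counting requires a
successful match — but a crossing that physically happens during a short
coast gap is caught at the next match, because the comparison spans the
gap.

Three mechanisms exist because a strict IoU gate and tiny objects
interact badly, which is worth stating quantitatively. For two
equal-size boxes offset by δ, IoU ≈ ((w−δx)(h−δy))/((w+δx)(h+δy)). At
the study geometry (sweep 4 px/frame, boxes 6–12 × 16–20 px) a Monte
Carlo over the size range gives, for a *perfectly predicted* box against
a detection with 1 px center jitter, P(IoU > 0.7) between 0.48 (smallest
boxes) and 0.88 (largest); at 2 px jitter, 0.09–0.35. A tracker that
insisted on the strict gate for every association would starve the
filter of updates and lose most identities. Hence:

- **Probation** (`confirm_hits`, default 5): a newborn track has no
  velocity estimate, so its one-frame prediction trails the object by a
  full sweep step — at this geometry that first pair sits at IoU ≈ 0.6,
  below the strict gate *even with a perfect detector*. Until a track
  has 5 matches (the number of cycles the filter needs to lock a
  velocity), association is gated at `tentative_iou_gate` (0.3, the
  classic online-tracking threshold).
- **Lenient re-acquisition**: the strict 0.7 gate expresses "same ear
  between consecutive frames". A confirmed track that coasted on the
  previous frame has an aged prediction and is re-acquired at the
  relaxed gate. Its dissolved sub-gate detection does not spawn a new
  identity (it is explained by the existing track); this is what
  prevents duplicate identities and double counts.
- **Scene-flow seeding**: because the camera sweep is global, the
  tracker estimates one shared velocity — the median nearest-neighbour
  displacement between consecutive detection sets, MAD-gated against
  mispairings, exponentially smoothed (weight 0.3), and replaced by the
  median velocity of locked-on tracks once at least three exist — and
  seeds every newborn track with it. This is the ego-motion compensation
  step standard in UAV tracking, and it is what makes sparse, noisy
  scenes trackable.

`max_age` defaults to 5 frames (≈0.17 s at 30 FPS): long enough to ride
out the dropout bursts a 10–30% per-frame miss rate produces, short
enough that a ghost track rarely survives to shadow a neighbour —
empirically, raising it to 8 starts producing over-counts from
long-lived ghosts, and dropping it to 1 (deleting a disappeared box
immediately) loses tracks at any realistic miss rate. `min_hits`
defaults to 1: an object is countable from its first successful match.

Known residual failure modes under heavy noise (30% miss, 2 px jitter):
objects that cross the baseline within the first few frames of the video
(no time to confirm a track), and objects clipped at the left/right
edges (reduced detection probability on partial boxes). These produce a
few-percent undercount that no gating choice removes; the acceptance
check therefore bounds the aggregate counting error over ten scenes
rather than requiring per-scene exactness at that noise level.

## Metrics

Detection evaluation is Pascal-VOC style: rank by confidence, greedily
match each prediction to the highest-IoU unclaimed truth of its own
image, TP iff IoU ≥ threshold (default 0.5, configurable — a matching
threshold for evaluation, distinct from the tracker's 0.7 association
gate). AP integrates the precision–recall curve with all-point
interpolation by default (the 11-point variant is available). The R² of
counts uses the total sum of squares about the truth mean; RMSE is the
plain root-mean-square count error. Degenerate cases (no truth, no
predictions, zero-variance truth) are reported as 0/flagged rather than
raising.

## Simulator

The generator emulates the acquisition geometry at a 5× downscale:
768×432 frames, sweep 4 px/frame (0.5 m/s at 30 FPS with the pixel
density fixed at 1200 px/m full-res — chosen so that a ~10 cm ear spans
~100–120 px full-res, consistent with the 30–100 px object sizes),
objects 6–12 × 16–20 px, object count drawn from 300–700 per video
scaled by the frame-area ratio (≈12–28 at default size; tests use 50–200
for denser scenes). Objects are static on a world strip; per frame the
window advances and every overlapping box is emitted, clipped, with a
`partial` flag. Ground truth includes the exact set of objects whose
center trajectory crosses the baseline.

The detector channel drops each true box with probability
`1 − detect_prob` (partial boxes use `detect_prob**2` — harder to
detect, yet a perfect detector stays perfect, keeping the identity
channel exact), jitters centers with Gaussian σ = `jitter_sigma` px and
log-sizes with σ = `jitter_sigma/size` (≈ the same noise in px, capped
at 50% relative for sub-pixel slivers), and adds Poisson false positives
per frame. One seed feeds five independent sub-generators (placement,
sway, dropout, jitter, false positives), so toggling one noise source
leaves the others' draws unchanged; everything is bit-reproducible given
the config.

What the simulator does *not* model — and therefore what green tests do
not establish about field data: occlusion and overlap between ears in a
real canopy, perspective and lens distortion, appearance-dependent
detector errors (confusion with awns/leaves), motion blur, non-constant
UAV velocity, and correlated (non-independent) detector failures. The
sway model is a per-object sinusoid, a crude stand-in for wind.

## Files and conventions

CSV files use the MOT dialect `frame,id,x,y,w,h,conf` with 1-based frames
and top-left-corner coordinates; internally frames are 0-based and boxes
center-form, converted at exactly one boundary (`earcount.io`). Floats
are written in shortest round-trip form so read→write is byte-stable.
LabelMe JSON rectangles are read (other shape types are skipped with a
warning). Every CLI run logs the package version, seed and a hash of the
effective configuration.
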