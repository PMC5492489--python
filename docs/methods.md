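# Methods

This note documents the models, rules and defaults implemented in
`bedwatch`, the assumptions behind them, and what the simulator-backed
tests do and do not demonstrate.

## Sensing model and units

All temperatures are integer sensor counts at 0.05 °C per count; "20
counts" is 1.00 °C. Frames arrive at 1 Hz as a 60-row × 80-column grid plus
one ultrasonic distance reading in cm, valid on [25, 220]; anything outside
is stored as the sentinel 221 ("beyond range"). Grid orientation is
row-major with (x, y) = (column, row), 0-based, and is enforced everywhere.
The pipeline assumes a single person in view and a static camera; the bed
region is supplied as a boolean mask rather than detected.

## Background and imprint

The background is the per-pixel arithmetic mean over N empty frames
(default: the first 10 frames of a recording) and is *static* thereafter —
there is no running update, so slow ambient drift over long recordings is
not compensated. The imprint is the set of pixels whose absolute deviation
from background strictly exceeds `threshold_counts` (default 20 = 1.00 °C).
Both warm and cold deviations count; a body colder than ambient would be
detected symmetrically.

## Residual-heat disposal

Residual heat — warmth left in bedding or flooring after the body moves —
must not contaminate the imprint-size features. The disposal step labels
the imprint into components (8-connectivity by default), tracks components
across frames by pixel overlap, and classifies each as body or residual:

* the component containing the frame's maximum deviation is presumed to be
  the body (the uncovered head is the hottest surface seen from above) and
  is protected;
* a component whose tracked peak *collapses* to at most `drop_fraction`
  (default 0.6) of its previous value has just lost the body — contact
  warmth is far cooler than the body itself — and is flagged immediately;
* a component whose peak has been non-increasing within
  `residual_tolerance_counts` (default 1) over `residual_confirm_frames`
  (default 3) consecutive observations, while not carrying the global
  maximum, is flagged as decaying residual;
* flagged regions stay flagged until their pixels drop below the imprint
  threshold; they are remembered for `linger_frames` (default 15) after
  vanishing and keep their full historical footprint, because a patch
  hovering at the threshold flickers in and out under sensor noise and its
  resurfacing fragments must keep matching the flagged track;
* a protected body that steps onto a flagged patch reclaims the merged
  component (its peak jumps up), so the person is never erased by their own
  residual trail.

Two consequences worth knowing: a patch that appears *after* the person has
already left the sensing area can only be flagged through the
peak-collapse or monotone-decay routes, and disposal is all-or-nothing per
component — when body and residual merge into one connected component the
residual pixels are retained until they decay or separate. Both mirror the
physical ambiguity rather than hiding it.

## Features

Per frame: `p_in`/`p_out` (filtered-imprint pixel counts inside/outside the
bed mask, which always partition the imprint), `t_in`/`t_out` (maximum raw
temperature over the filtered imprint on each side; for a side with no
imprint the value falls back to the background's maximum over that side —
roughly ambient — so classifiers always receive a number), `d` (the
distance reading), and `m` (the symmetric set difference between the
current and previous filtered masks; 0 for the first frame).

## Classification

Location uses (`p_in`, `p_out`, `t_in`, `t_out`); posture additionally uses
`d` and the location, one-hot encoded. Families:

* **mlp** — two hidden layers of 6 and 4 logistic units, SGD with learning
  rate 0.2 and momentum 0.1, weight-init seed 42 by default (exposed in the
  spec of each model). The tiny network occasionally lands in a poor basin
  for particular init seeds; the init seed is a model hyperparameter, not a
  data seed.
* **knn** — Euclidean k-NN, k odd (7 for location, 3 for posture by
  convention). Voting ties resolve to the lowest class index in the fixed
  order None < Bed < Bedrail < Floor (locations) and None < Laying <
  Sitting < Standing (postures).
* **tree** — an entropy-criterion decision tree with optional
  cost-complexity pruning (`ccp_alpha`), standing in for classic
  C4.5-style trees; exact equivalence with gain-ratio/reduced-error
  implementations is not attempted.

Inputs to mlp and knn are min–max scaled with ranges fitted on the learning
set. Models serialize to self-describing JSON (knn: the scaled training
table; tree: the split arrays; mlp: layer weights), so persistence needs no
pickling and loaded models predict identically.

Per-frame plausibility rules then run in order: (Bed|Bedrail, Standing) is
physically impossible and marks the frame erroneous; a one-sided None is
widened to (None, None) and accepted; a distance reading outside the
configured compatibility interval for the (location, posture) pair marks
the frame erroneous. Default intervals, for a ceiling ≈ 220 cm above the
floor: Standing [40, 110]; Sitting [90, 170]; Laying in Bed/Bedrail
[130, 190]; Laying on Floor [170, 221]. The intervals are configuration,
not physics — they encode this room geometry and should be re-derived for
another mounting height.

## Event engine

A candidate (location, posture) run grows by one per accepted matching
frame; a different accepted pair restarts it; erroneous frames are
dismissed and do not advance or reset it, up to `max_dismissals` per window
(default: the largest window length), beyond which the window aborts. When
the run reaches the window length applicable to the transition from the
previous stable state, the new stable state is confirmed at that frame and
the matching events are emitted: Area Entry/Exit at N = 5, Fall and Bed
Entry/Exit at N = 10. One transition can emit several events, each at its
own window length — (None,None) → (Bed, Laying) yields AreaEntry at the 5th
accepted frame and BedEntry at the 10th; Bed → Floor + Laying yields both
BedExit and Fall. The engine starts from a (None, None) stable state
(recordings begin with the empty room used for background estimation); a
different start can be injected.

Fall recognition can be gated on physical evidence (both gates default on,
and are disabled when the engine is fed ground-truth labels): the maximum
`m` in the transition window must reach `mf_spike_fraction` (default 0.2)
of the mean imprint size there, and — for falls out of bed — some ordered
frame pair in the window must show `p_in` dropping by `bed_drop_fraction`
(default 0.5) while `p_out` rises. The window extends `gate_lookback`
(default 5) frames before the run start, because the imprint collapse
happens at the transition frame itself, before the new candidate run
begins; and the pixel collapse may be spread over two frames by the
disposal step's one-frame admission latency, which is why the gate compares
any ordered pair rather than only consecutive ones.

(Bedrail, Laying) has no event type of its own; any event confirming that
state carries `hazard_flag=True` and the engine records the confirmation
frame.

## Evaluation

Detected events are matched greedily one-to-one to actual events of the
same type within ±`tolerance` frames (default 15, i.e. 15 s at 1 Hz);
for interval matching on sorted lists this greedy matching is maximal.
True negatives are non-event *opportunities* supplied by the evaluation
protocol, not derivable from frames. Metrics are exact rational
percentages rounded half-up to two decimals; FPR and FNR are computed as
100 minus the rounded specificity and sensitivity, so the complement
identities hold exactly. Ratios with empty denominators return None.
Combined "best algorithm per class" rates pick the maximum per-class
correct count across families and divide by the set size (the headline
combined location rate is conventionally quoted at integer precision).

## Simulator

The simulator renders what the sensor pair would plausibly see, not what a
radiometric camera would record. Defaults (all configurable in
`SceneConfig`): ambient 420 counts (21 °C); body as two axis-aligned
Gaussians — torso spread per posture, a σ = 1.8 px head offset along the
body axis — with amplitudes 150 (torso) and 120 (head hotspot) counts over
ambient, thresholded at 20 counts into silhouettes of roughly 40 px
(Standing), 120 px (Sitting) and 260 px (Laying); contact surfaces under
the body hold a residual amplitude of 80 counts that decays exponentially
with τ = 20 s once vacated; iid Gaussian noise of σ = 2 counts (0.1 °C),
rounded to integers; distance = the nearest surface inside the ultrasonic
cone (body top when the body is in the cone, else the empty bed at 180 cm),
with posture-specific body-top distances placed at the midpoints of the
classifier's compatibility intervals so simulator and sanitizer agree, plus
±2 cm jitter. Scenario scripts are (location, posture, position, duration)
segments; ground-truth events derive from segment transitions with the same
transition taxonomy the engine uses, anchored where the corresponding
stable-state window completes. Everything is bit-deterministic per seed.

What the simulator does *not* emulate — and therefore what passing tests do
not show about field data: lens vignetting and optics, sunlight or
air-conditioning confounders, multiple people, gradual (non-teleport)
motion between postures, ambient drift, and real bedding thermodynamics.
The end-to-end accuracy figures on simulated data characterize the
pipeline's mechanics under the stated conditions, not expected clinical
performance.

## Problem sizes used in the checks

The packaged acceptance run trains on three simulated scenario recordings
(~550 frames) and evaluates on ten fresh scenarios (~1100 frames); the
ground-truth event-recovery property uses 20 scripted scenarios. These
sizes give stable statistics (location accuracy typically 95–99 %, Fall
sensitivity 1.0 across seeds) while keeping the whole run to seconds.

## Known limitations

* The residual/body decision is heuristic; simultaneous residual patches
  connected to the body are not separated.
* A cold room whose "residual" warms toward ambient from below is treated
  symmetrically through the absolute deviation, but the peak-collapse
  trigger is tuned to cooling contact warmth.
* The event engine recognizes at-least-N stability; events faster than
  their window (a person crossing the area in under 5 s) are invisible by
  construction.
* Classifier accuracies on the original hospital recordings cannot be
  reproduced — the recordings were never published; only the printed
  evaluation arithmetic is reproduced exactly.
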