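# Methods

This note documents the science and the engineering decisions inside
`gaitlidar`: the measurement model, what each stage assumes, which knobs
matter, what the simulator does and does not emulate, and where the open
design choices were settled.

## Measurement model

A planar lidar at shin height reports, 40 times per second, a fan of 2161
range readings over a 270° field of view at 0.125° resolution. A walking
person appears as one or two small arcs of returns (the laser sees only the
sensor-facing surface of each shin, modelled here as a 6 cm-radius disc).
Everything else — walls, furniture — is static. The pipeline turns this
into heel-strike events and six spatiotemporal gait parameters.

### Resampling

Sensors are resampled onto a common uniform clock by linear interpolation
*per beam in polar space*: beams are the sensor's native channels and stay
in correspondence across revolutions (matched by angle; beams missing from
either bracketing scan are dropped for that instant). When the two
bracketing ranges differ by more than 0.5 m the beam has crossed an
occlusion edge — something moved into or out of it — and blending would
fabricate a phantom return in mid-air; the beam instead takes the return of
the temporally nearer scan. Taking the nearer-*range* return here is
tempting but wrong: it projects the next revolution's leg returns into the
current frame and duplicates a moving leg.

### Sensor alignment

One sensor is the reference frame. For every other sensor, a binary raster
(5 cm cells) of the union of 50 randomly sampled frames is matched against
the reference's raster with SIFT (the binary image is Gaussian-blurred,
σ = 1.5 px, to give the detector usable gradients). The matched keypoints,
converted to metric coordinates, feed a closed-form least-squares rigid fit
(`θ = atan2(Σ p×q, Σ p·q)` on centred coordinates), wrapped in a robust
loop that drops the worst-residual pair and refits until the maximum
residual is below two raster cells (never below three pairs, duplicates
collapsed). Reflections are impossible by construction, and scale is fixed
at 1 — all sensors measure the same metric space.

Using the *union* of sampled frames means the walking person leaves a faint
smear in the raster; the ratio test and the robust refit reject matches on
it. An occupancy-majority raster (cells set in ≥ 50 % of samples) was tried
instead and performed *worse*: marginal wall cells flicker around 50 %
occupancy and the wall lines dissolve into speckle that starves SIFT of
stable keypoints.

Alignment accuracy on simulated two-sensor rooms is a few centimetres and
well under a degree — sub-cell, as expected, and small against the 25 cm
scale of a shin.

### Motion segmentation

Per-cell occupancy is the fraction of 200 randomly sampled frames (without
replacement, seeded) containing at least one return; cells at ≥ 0.5 are
background, then closed with a disk of 10 cm radius to bridge the gaps
between adjacent beam hits on walls. Thresholding *before* closing is this
package's choice (the alternative order is not meaningfully different on
walls, but closing a fractional image would blur the threshold semantics).
Two numerical details:

* The mask is the union of closings with all digital disks up to the
  requested radius. Digital disks are not nested scalings of each other, so
  a single closing is not monotone in the radius; the cumulative union
  restores the invariant "a larger closing radius never shrinks the mask".
* Legs transit any cell briefly (a stance occupies a cell for ~1.2 step
  times, well under half of a recording), so they never enter the mask; no
  person-free calibration recording is needed.

Residual leakage is expected where walls are seen at grazing incidence:
1 cm range noise smears hits many centimetres *along* such walls, leaving
cells that flicker below the occupancy threshold. These stray foreground
points arrive as small, spatially stable clutters far from the walkway and
are rejected downstream (size band, tracking gate).

### Leg tracking

Foreground points are clustered by average-linkage agglomerative clustering
(Euclidean). Merging stops at the 0.3 m linkage threshold — roughly the
distance between two legs — or when four clusters remain (two legs plus two
to absorb noise), whichever binds first; i.e. the dendrogram is cut at
min(height of the 4-cluster partition, 0.3 m). The floor matters: the two
legs' clouds pass within 0.3 m of each other at every stride, and cutting
purely at the threshold would fuse them at each crossing. Clusters outside
5–50 points are discarded.

Centroid pairs closer than 25 cm — about the maximum diameter of a leg —
are merged (pooled-point centroid), at any cluster count: two centroids
that close are one leg, whether they came from the four-cluster floor
splitting an arc or from two legs colliding. The remaining scenarios:

* **two clusters** — k-means (k = 2, seeded at the agglomerative centroids,
  tolerance 1e-6, deterministic) refines the centroids on the pooled points;
* **more than two** — the two largest by point count are kept;
* **fewer than two** — the missing leg is predicted from its last known
  position plus a clamped backward difference (≤ 10 cm/frame, i.e. 4 m/s at
  40 Hz, averaged over up to three preceding frames so a single noisy fix
  is not extrapolated verbatim). A single cluster within 0.4 m of *both*
  predictions (themselves within 0.4 m of each other) is the two legs fused
  while passing; its centroid is the pair's midpoint, not either shin, so
  both legs ride on prediction until they separate.

Identity is maintained by matching observations to each slot's *predicted*
position (during a swing the shin moves 10–15 cm per frame; the stale last
fix is the wrong reference). Clusters farther than 0.5 m from both
predictions are ignored as noise, and the first acquisition requires two
centroids within 1 m of each other — one person's legs. A streak of more
than 20 fully predicted frames (0.5 s) ends the walking bout instead of
extrapolating on.

Left/right naming: once the body centre (midpoint of the two centroids) has
travelled ≥ 5 cm, the leg whose offset from the body centre has a positive
`cross(direction, offset)` z-component is "left". The convention only
affects naming, never parameter values.

### Gait analysis

Each leg's scalar speed series (‖Δcentroid‖ · rate, cm/s, timestamps at
interval midpoints) is median-filtered with windows of 5 then 9 samples
(reflected edges): wide enough to kill 1–2-sample tracking jitter, narrow
enough to keep 250–400 ms swing peaks intact. Three detectors follow:

* **major peaks** — prominence ≥ 100 cm/s, ≥ 0.4 s apart: the swings. Every
  plausible swing peaks above ~170 cm/s, while partial-occlusion centroid
  jitter of a stance leg stays below ~100 cm/s prominence; 100 separates
  the bands. (50 cm/s was tried first and admits occlusion jitter.)
* **minor peaks** — prominence in [10, 100) cm/s after the first major
  peak: the shin rolling forward over the planted foot mid-stance.
* **valleys** — maximal runs of filtered speed ≤ 25 cm/s: the stances.

The heel strike of a swing is the median timestamp of the first valley
after its major peak (and before the next one), truncated at the first
minor peak inside the valley; its position is the *raw* centroid
interpolated at that time — filtering is for event timing only. Emitting at
most one strike per swing is deliberate: noisy stance valleys can fragment,
and per-valley emission would double-count stances. The detected strike
time sits a fixed fraction of the stance after the true foot-fall; because
the leg is stationary throughout the stance, the position is exact and the
constant time offset cancels in every interval-based parameter.

Parameters follow from the strike sequence (means over events; series
retained): step metrics from consecutive contralateral strikes
(non-alternating pairs are skipped and logged), stride metrics within each
leg, cadence = (n−1)/elapsed·60, and walk velocity = strike-to-strike path
length / elapsed — identical to straight-line displacement on straight
walks, and the more honest "total ambulation" on curved ones.

## The simulator: what a green test establishes

The simulator ray-casts exact wall/prop/disc geometry with seeded Gaussian
range noise per beam, and its walker is a *stated world*:

* strikes every `T = 60/cadence` seconds at multiples of the step length
  along a straight line, alternating legs, footholds offset ±0.12 m
  laterally; the right leg swings first after a 0.6 s standing lead-in;
* stance pins the shin at its foothold for 60 % of the gait cycle; swing
  moves it to the next foothold with a raised-cosine speed profile (zero at
  lift-off and strike);
* mid-stance, the shin advances ~9 cm with a raised-cosine bump peaking at
  45 cm/s over 0.4 s — the ankle-rollover micro-motion that the minor-peak
  detector keys on. Weaker/shorter bumps (≤ 15 cm/s, 0.1 s were tried) are
  annihilated by the double median filter or drowned by the ~15 cm/s stance
  speed-noise floor at 1 cm beam noise, which would leave end-of-walk
  stance valleys unbounded and bias stride time;
* before gait onset the feet rest 0.35 m apart (a relaxed wide stance):
  shins at walking width (0.24 m) merge under the 0.3 m linkage threshold
  and tracking could only acquire mid-swing, losing the first step;
* ground-truth gait parameters are computed from the true strike events
  with the same formulas as the measured side — note the true step length
  is `sqrt(L² + 0.24²)`, not the configured forward progress `L`, exactly
  as a walkway measuring heel positions would report it.

The `straight_walk` preset uses two sensors on opposite walls of an
8 m × 6 m room: when a crossing leg occludes its partner from one side the
other sensor still sees it (the study setup this emulates used three
sensors for the same reason). The room is sized so the combined per-leg
beam count stays under the 50-point cluster cap. The `occluded_walk` preset
is deliberately single-sensor with a narrow pillar whose shadow on the
walking line is ~15 cm wide and lies between two footholds: each swinging
leg blinks out for ~3 frames, exercising the prediction bridge.

What the simulator does **not** emulate: torso/arm returns, non-circular
shin cross-sections, gait asymmetry and variability (every simulated step
is identical), curved paths, sensor timing jitter, multi-path and intensity
effects, and more than one person. A green recovery test therefore
establishes that the *algorithmic chain* is correct and noise-robust under
the stated kinematics — not that the pipeline handles pathological gait or
cluttered multi-person scenes.

Systematic residual: recovered stride/step lengths are ~1.5 % short. The
visible-arc centroid of a disc sits ~0.6 r closer to the sensor than the
disc centre, and the direction of that bias rotates as the walker crosses
the field of view, shortening strike-to-strike distances slightly — the
same "slightly too short" spatial bias reported for shin-height lidar
measurements against walkway references.

## Agreement statistics

Classical formulas with sample (n−1) standard deviations throughout: paired
t on the differences (dof = n−1, Cohen's d = |mean diff| / sd diff;
zero-variance differences with nonzero mean report an infinite t rather
than raising), OLS of system B on system A with the F-test against the
intercept-only model, Pearson r (r² equals the regression R² to 1e-12 by
construction), RMSE / SE / t-based 95 % CI of the mean difference, and
Bland–Altman bias ± 1.96 sd with the per-pair (mean, difference) table.
Multiple testing across the six parameters uses Bonferroni — conservative
and explicit; the default significance level is α = 0.01. Qualitative
correlation labels ("very strong" ≥ 0.9, …) are for report text only.

## Tunable parameters

| parameter | default | unit | why |
|---|---|---|---|
| scan rate | 40 | Hz | study hardware |
| raster cell | 0.05 | m | walls are ≥ 10 cm structures; sub-cell alignment error is small vs a 25 cm shin |
| background frames | 200 | — | stochastic average stabilises at a few hundred samples |
| occupancy threshold | 0.5 | — | static structure is present in ~every frame; legs in < 15 % |
| closing radius | 0.10 | m | bridges beam-to-beam gaps on walls at typical range |
| linkage threshold | 0.3 | m | the distance between two legs |
| expected clusters | 4 | — | two legs + two to absorb noise |
| cluster size band | 5–50 | points | a shin subtends 9–45 beams at 1.5–6 m |
| centroid merge | 0.25 | m | maximum diameter of a leg |
| prediction clamp | 0.10 | m/frame | 4 m/s plausibility bound at 40 Hz |
| max predicted streak | 20 | frames | 0.5 s; longer means the person is gone |
| median windows | (5, 9) | samples | kills jitter, keeps swing peaks |
| major prominence | 100 | cm/s | above occlusion jitter, below every swing |
| minor prominence | 10 | cm/s | above the filtered stance noise floor |
| valley threshold | 25 | cm/s | stance is near-zero speed |
| peak separation | 0.4 | s | swings of one leg are ≥ 0.9 s apart |
| α | 0.01 | — | study significance level |

## Known limitations

* Single person, mostly straight walks; no Kalman filtering, no multi-person
  data association.
* Heel-strike *times* carry a constant offset into the stance (≈ 0.1–0.3
  step times); absolute event timing against an external clock would need a
  correction, though no interval or position quantity is affected.
* The hard-coded detectors assume the stance/swing speed contrast of
  able-bodied gait; shuffling gait with swing peaks below ~1 m/s would need
  retuned prominence bands (they are all configuration entries).
* Background estimation assumes the scene is static for the duration of a
  recording; moved furniture contaminates the mask.
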