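# Methods

## Pipeline overview

`faceaoi` maps gaze recordings onto moving facial Areas of Interest (AOIs)
in four stages:

1. **Center derivation** (`aoi_centers`): each AOI — left eye, right eye,
   nose, mouth — is represented per video frame by one cell center, the
   arithmetic mean of a fixed subset of the 68 standard facial landmarks
   (left eye 37–42, right eye 43–48, nose tip 31, inner-lip midpoints
   63 and 67; 1-based numbering). Averaging the six eye-outline landmarks
   puts the center in the middle of the palpebral fissure; the two inner-lip
   midpoints straddle the mouth opening.
2. **Gaze-to-AOI assignment** (`lrvt`): limited-radius Voronoi tessellation.
   A sample is assigned to the nearest center in Euclidean pixel distance if
   that distance is at most the radius, else to the catch-all `non` AOI.
3. **Measures** (`dwell_metrics`, `paired_gaze`): dwell statistics per AOI
   (plus a combined `eyes` AOI) and, for dyads, per-sample mutual-gaze
   states with episode statistics.
4. **Validation** (`track_validation`): statistics for comparing two center
   tracks of the same video and for temporal stability, plus blink-spike
   detection and filtering.

Key assumptions: one frontal face per video; a flat screen viewed frontally
at a fixed distance; gaze and video share a clock up to a constant offset
(configurable, default 0); landmark coordinates and gaze are in the same
pixel space (origin top-left, y down). "Left eye" always means the eye on
the left of the image.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `radius_deg` | 4 | deg visual angle | large Voronoi cells are the robust choice for sparse face stimuli; 4° ≈ 200 px on the reference screen |
| `boundary_inclusive` | true | — | "within radius" read as ≤ |
| `tie_order` | left eye, right eye, nose, mouth | — | deterministic tie-break; exact ties have measure zero |
| `max_gap_frames` | 12 | frames | ≈0.5 s at 25 fps; short detector dropouts are bridged by carrying the last centers forward, longer ones become missing |
| `min_confidence` | 0 | — | detector success flag only; no confidence threshold by default |
| `gap_tolerance_s` | 0 | s | dwell segmentation does not bridge missing data unless asked |
| `min_dwell_s` | 0 | s | no minimum-duration filter by default |
| join `tolerance_s` | half the coarser sample interval | s | nearest-neighbour join of two gaze clocks; partners farther away count as missing |
| spike `window` | 7 (9 used in validation runs with motion) | frames | odd, centered; long enough to out-vote a 1–3-frame blink |
| spike `n_mad` | 3 | — | conventional Hampel threshold in scaled-MAD units |

Screen geometry is given as resolution, physical size and viewing distance;
alternatively the distance is inferred in closed form from the width and its
angular extent, d = (w/2)/tan(θ/2). For the reference 22-inch screen
(1680×1050 px, 47.38×29.61 cm, 32.61° wide) this yields ≈81 cm; that value
is a reconstruction consistent with the printed extents, not a measured
distance.

## Numerical choices

- **Pixel↔degree conversion** is tangent-exact, `θ = 2·atan(n·pitch/(2d))`,
  not the small-angle approximation; only the exact form reproduces the
  full-screen angular extents. Off-center extents use the same centered
  formula (eccentricity ignored): on a desktop display at ~80 cm the error
  is negligible for the central region a face occupies.
- **Radius conversion** to pixels happens once, on the horizontal axis; the
  pixel pitch of common displays is near-isotropic, so no per-axis or
  per-sample eccentricity correction is applied.
- **Frame alignment**: a sample at time t maps to frame
  `floor((t − offset)·fps)`, clamped to the track with a flag. A 1 ns guard
  keeps samples that land exactly on a frame boundary in the frame that
  starts there despite float rounding.
- **Dwell durations**: each sample occupies one sample interval, so a
  one-sample dwell lasts 1/rate and dwell time + missing time tiles the
  recording exactly — conservation is exact by construction, not up to an
  edge convention.
- **Combined eyes**: totals are additive over the two eye AOIs; for counts
  and means, temporally adjacent left/right dwells merge into one `eyes`
  dwell (adjacency tested with a 1 µs tolerance on float timestamps).
- **RMS stability** is computed on sample-to-sample differences by default,
  not about the mean: the question it answers is whether a coordinate is
  stable from one frame to the next, and an about-mean RMS would be
  dominated by genuine slow head motion. The about-mean variant is
  available as `mode="about_mean"`.
- **Spike detection** is a Hampel rule with the scale estimated per window:
  a frame is flagged when a monitored coordinate deviates from its centered
  rolling-window median by more than `n_mad` × 1.4826 × (median absolute
  deviation within that window, about that window's median). Only the eye
  AOIs are monitored by default, since blinks displace only the eye
  landmarks. Filtering replaces flagged frames by linear interpolation
  between the nearest unflagged neighbours (nearest-neighbour extension at
  the ends) or by the window median; unflagged frames are bit-identical.
  The spike filter is off by default in the pipeline — the validation
  statistics are meant to be computed on the raw signal, and filtering is
  opt-in.
- **Missing data** never contributes to any metric: invalid gaze samples
  and frames without centers are labelled `missing`, missing partners make
  a dyadic sample `undefined`, and both are reported separately so that the
  labelled/classified times plus missing/undefined time always add up to
  the session duration. Absence of data is not treated as evidence of
  looking away.

## The synthetic-data generator

`synthetic` exists so that every stage can be tested against known ground
truth without any video. It emulates:

- a 68-point landmark track: a hard-coded anatomically plausible template
  face (≈300×400 px; eye centers 150 px apart, nose tip 121 px from each
  eye center, mouth center 105 px below the nose tip) rigidly translated by
  per-axis sinusoids (default amplitudes 20 and 10 px, periods 4 and 3 s —
  smooth conversational head motion at 25 fps) with i.i.d. Gaussian jitter
  (default SD 0.5 px, the scale of landmark-detector noise);
- blinks: rectangular displacement pulses on the eye landmarks only,
  downward and toward the face midline (default 5 px inward, 10 px down,
  1–3 frames), mimicking how eyelid closure drags the detected eye outline;
- gaze: a dwell schedule targeting AOI centers (or an off-face point) plus
  Gaussian noise, sampled at a configurable rate (default 100 Hz) with
  i.i.d. sample dropout;
- dyads: both participants' gaze derived from one shared schedule of
  mutual-gaze states, with the true paired-state stream recorded.

Ground-truth centers always come from the noiseless, blink-free trajectory.
All generators draw from one seeded generator per call: equal seeds give
bit-identical output.

What the generator does **not** emulate: non-rigid facial deformation
(talking, expressions), head rotation and scale changes, realistic eyelid
kinematics, correlated or drifting eye-tracker error, saccades between
dwells, and detector failures correlated with motion. Passing recovery
tests therefore show that the pipeline's bookkeeping is exact under its own
model of the data — schedule in, schedule out — not that landmark detection
works on real video, which is outside this package's scope (it consumes
detector output, it does not produce it).

## Design decisions that were genuinely open

- **Gap policy for failed detections**: carry the last valid centers
  forward across runs of at most `max_gap_frames` failed frames (flagged
  `carried`), longer runs become missing. A leading failed run is never
  carried. Alternative (`mark_missing`) is available.
- **Dwell definition around missing data**: a dwell is a maximal
  same-label run; missing runs up to `gap_tolerance_s` flanked by the same
  label may be bridged (default: not bridged). The bridged gap's samples
  are not counted in `n_samples`, so sample-count bookkeeping stays exact
  at tolerance 0.
- **Dyadic "frequency"**: reported both as the episode count and as
  episodes per minute, since either reading is defensible.
- **Join of two gaze clocks**: the joint timeline is the coarser stream's;
  resampling the finer stream avoids inventing samples the slower recorder
  never took.

## Problem sizes

Synthetic runs in the tests and the acceptance script use 10–12 s of video
at 25 fps (250–300 frames) and gaze at 100–1000 Hz (10⁴–1.2×10⁴ samples for
the accuracy checks), with 10⁴ random configurations for the assignment
oracle. These sizes give exact recovery checks and tight stochastic bounds
(binomial SE < 0.1 % at n = 10⁴) while keeping the whole suite in seconds.

## Known limitations

- One face per video; no multi-face disambiguation.
- The centered-angle approximation ignores gaze eccentricity; for very
  large screens or short viewing distances the radius in pixels would vary
  across the screen.
- Carried-forward centers freeze the face during dropouts; long dropouts
  (beyond `max_gap_frames`) correctly become missing, but brief large
  motions during a dropout are not recovered.
- The Hampel detector needs the blink displacement to exceed the
  motion-plus-noise MAD floor in its window; blinks during fast head
  motion can fall below threshold.
- No fixation/saccade event detection: all measures are computed on raw
  samples, which is the intended level of analysis here.
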