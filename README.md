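# faceaoi

Automatic Areas-of-Interest (AOIs) for eye-tracking studies that use videos
of a face. When the stimulus moves — a talking, blinking, head-turning face —
AOIs must follow it on every video frame, which is prohibitively slow to do
by hand. `faceaoi` turns per-frame 68-point facial-landmark tracks (the
standard output of modern landmark detectors such as OpenFace) into moving
AOIs for the left eye, right eye, nose and mouth, maps gaze recordings onto
them, and computes the dwell-time and dyadic mutual-gaze measures that
face-scanning and social-interaction research works with.

## Who it is for

Eye-tracking researchers studying gaze to faces: screen-based face-processing
experiments, and two-way video ("dyadic interaction") setups where each
participant watches a live video of the other and per-pair mutual-gaze
measures are needed.

## The method

**AOI cell centers.** Each facial AOI is reduced to a single cell center per
video frame: the arithmetic mean of a fixed subset of the 68 landmarks
(1-based standard numbering):

| AOI       | landmarks |
|-----------|-----------|
| left eye  | 37–42     |
| right eye | 43–48     |
| nose      | 31 (tip)  |
| mouth     | 63, 67    |

"Left eye" is the eye on the left of the *image* (viewer perspective).

**Limited-Radius Voronoi Tessellation (LRVT).** A gaze coordinate g is
assigned to the AOI whose center c minimizes the Euclidean distance ‖g − c‖,
provided that distance does not exceed a radius r (default 4° of visual
angle, converted to pixels from the screen geometry); otherwise it falls in
the "non" AOI:

    label(g) = argmin_i ‖g − c_i‖   if min_i ‖g − c_i‖ ≤ r,  else "non"

**Measures.** Dwells are maximal runs of samples with one label; per AOI the
package reports total dwell time, mean dwell time and number of dwells,
including a combined *eyes* AOI. For dyads, each joint time point is
classified as *two-way eye gaze* (both partners on the eyes), *one-way eye
gaze* (exactly one) or *no eye gaze* (neither), with undefined where data
are missing.

**Validation statistics.** For comparing two center tracks of the same
video: per-AOI/axis mean and maximum absolute coordinate difference, and
RMS of sample-to-sample differences (temporal stability), in pixels and
degrees. Blink artifacts — brief displacements of the eye centers downward
and toward the face midline — can be detected with a Hampel
(rolling-median/MAD) rule and filtered out.

## Worked example

Everything below runs on synthetic data with known ground truth — no video
required. Simulate a 10-second face video (25 fps, smooth head motion) and a
gaze stream that dwells 2 s each on the left eye, nose, mouth, an off-face
point, and the right eye; then run the pipeline:

```sh
faceaoi simulate --out-dir demo --seed 42
cat > demo/cfg.yaml <<'YAML'
screen:
  width_px: 1680
  height_px: 1050
  width_cm: 47.38
  height_cm: 29.61
  width_deg: 32.61
YAML
faceaoi extract-centers --landmarks demo/landmarks.csv --out demo/centers.csv
faceaoi map-gaze --centers demo/centers.csv --gaze demo/gaze.csv \
    --config demo/cfg.yaml --out demo/labels.csv
faceaoi metrics --labels demo/labels.csv --out demo/summary.csv
cat demo/summary.csv
```

which prints

```
label,total_dwell_time_s,mean_dwell_time_s,n_dwells
left_eye,2,2,1
right_eye,2,2,1
eyes,4,2,2
nose,2,2,1
mouth,2,2,1
non,2,2,1
```

Each scheduled 2-second dwell is recovered exactly: one dwell per AOI, the
off-face segment lands in `non`, and the combined `eyes` AOI totals 4 s over
two dwells (the left- and right-eye dwells are not adjacent in time, so they
stay separate dwells). On this screen (47.38 cm wide, subtending 32.61°, so
viewed from ≈81 cm) the 4° radius is 200.6 px.

For a dyad, `faceaoi paired --labels-a a.csv --labels-b b.csv --out
paired.csv` adds the two-way/one-way/no-eye-gaze summary, and `faceaoi
validate --track-a x.csv --track-b y.csv --geometry cfg.yaml --out
report.csv` compares two center tracks. `faceaoi run --config cfg.yaml
--out-dir out/` chains everything from one YAML file.

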