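# alcv

Quantification of anterior lens capsule vascularity (ALCV) from
retroillumination eye images, and gestational-age (GA) prediction from the
resulting vascular biomarkers.

Under retroillumination the embryonic lens vasculature of preterm infants
appears as dark branching vessels on a bright red pupil reflex; the degree
of its regression tracks gestational age. This package implements the full
analysis chain:

- **`alcv.synthetic_eye`** — synthetic retroillumination scenes with exact
  ground truth (pupil geometry, vessel trees of known length/width/
  tortuosity, blur/noise/artifact degradations) plus a repeated-measures
  cohort simulator. All testing runs on synthetic data.
- **`alcv.pupil_detection`** — circular-Hough candidate generation, best
  candidate selection by weighted voting of contrast/circularity/color,
  and RGB+HSV boundary refinement.
- **`alcv.vessel_segmentation`** — percentile contrast stretching of the
  red/green channels inside the pupil, hysteresis thresholding, and a
  manual-tuning hook with recorded parameters.
- **`alcv.vessel_morphometry`** — skeletonization, branch decomposition
  with spur pruning, per-branch length/width/box-counting fractal
  tortuosity, and the eight session-level biomarkers.
- **`alcv.ga_model`** — fixed-coefficient GA predictor (shipped as a
  versioned JSON coefficients file), random-intercept mixed-model fitting
  by profile maximum likelihood, VIF screening, Hittner grade lookups, and
  Bland–Altman agreement statistics.
- **`alcv.pipeline` / `alcv.cli`** — end-to-end orchestration with QC
  accounting and a `click` CLI.

## CLI

```sh
alcv synth --out scenes/ --n-scenes 3 --seed 1 --cohort-subjects 24
alcv detect scenes/scene_000.png --out pupil.json --overlay overlay.png
alcv quantify scenes_video_dir/ --subject S1 --session V1 --out features.csv
alcv predict features.csv --out predictions.csv
alcv agree predictions.csv --out report/
alcv fit cohort.csv --out mixedfit.json
```

A "video" input is an MP4/MOV container (requires an ffmpeg-capable
imageio backend), a single still, or a directory of ordered frame images.
Exit codes: 0 success, 2 quality-control failure (e.g. no detectable
pupil), 1 error. Pipeline parameters live in a single YAML config
(`--config`); unknown keys are rejected.

## Notes

- The shipped coefficients are unit-convention-dependent: the feature
  scale underlying the published estimates is not fully specified, so the
  coefficients file declares its `feature_units` and an explicit
  coefficient-to-feature `mapping` ("width" = perpendicular bounding
  extent, "thickness" = distance-transform caliber) that is validated at
  load time. Refitted models are drop-in replacements.
- Branch length is reported as a chord-resampled polyline length of the
  skeleton path; the raw 1/√2 chain-code sum is available as
  `Branch.step_length` (it overestimates digital curve length by up to
  ~8%, which would break the stated recovery tolerances).
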