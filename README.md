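# wormlapse

Quantitative analysis of long-term time-lapse microscopy of *C. elegans*
post-embryonic development.

Larvae developing in hydrogel microchambers can be imaged every 20 minutes
for the full ~40 h from hatching to adulthood, but the animal keeps moving
and growing, so raw camera coordinates are meaningless across frames.
`wormlapse` implements the analysis layer that makes such movies
quantitative:

* **Body-axis geometry** — a spline centre line is fitted through 10–20
  manually annotated points per frame; every position is expressed in body
  coordinates (s, t), where *s* is the arc length along the anteroposterior
  axis (µm) and *t* the signed dorsoventral offset (µm, *t* < 0 ventral).
  The same transform computationally straightens images and gives the body
  length *L* per frame.
* **Developmental staging** — hatch plus the four ecdysis times define each
  animal's timeline; times map to larval stages L1–L4 with half-open
  intervals, and population ecdysis fractions are histogrammed per time bin.
* **Seam-cell lineage statistics** — divisions carry a class
  *d* ∈ {0 none, 1 symmetric, 2 asymmetric}; the package computes relative
  division times ΔT<sub>i</sub> = T<sub>i</sub> − ⟨T⟩ within an animal and
  stage, animal-to-animal variability, and the mutant lineage-error
  probability P(l, s) = ⟨1 − δ(d<sup>WT</sup>, d<sup>M</sup>)⟩ over cells
  shared between the reference and each mutant — cells created by an
  upstream error are excluded, so each sub-lineage is scored only at its
  first deviation.
* **Distal-tip-cell migration** — (s, t) trajectories relative to a
  stage-appropriate origin (midbody for L1–L3, vulva for L3–L4), Δs marker
  correction for inter-Z-slice body movement, 1 h sliding-average smoothing,
  v<sub>A–P</sub>/v<sub>D–V</sub> velocities, ecdysis alignment and
  midline-crossing detection.
* **Oscillatory gene expression** — A–P kymographs (|t| < 60 µm window,
  % body length bins), regional traces (5% of body length at 25/50/75%),
  Otsu-masked single-nucleus intensities (5 µm × 5 µm ROI), per-stage
  expression peaks after 1 h Gaussian filtering, peak timing relative to
  ecdysis, and pairwise trace correlations.
* **Synthetic movies** — a ground-truthed generator (bent growing body,
  scheduled seam-cell divisions, migrating DTC pair, per-stage expression
  pulses peaking 1.1 h before each ecdysis) exercises every analysis path
  without any external data.

## Worked example

```python
import numpy as np
from wormlapse import (WormConfig, generate_movie, stage_durations,
                       ExpressionTrace, detect_stage_peak,
                       peak_relative_to_event, detect_midline_crossing)
import wormlapse.annotations as A

movie = generate_movie(WormConfig(seed=1), render=False)
tl = movie.truth.timeline
print("stage durations (h):", np.round(stage_durations(tl), 2))

axes = A.fit_axes(movie.annotations)          # spline per annotated frame
print("body length at hatch / L4 ecdysis (um): %.1f / %.1f"
      % (axes[0].length, axes[-1].length))

cross = {k: detect_midline_crossing(v) for k, v in movie.truth.dtc.items()}
print("DTC midline crossings (h):", {k: round(v, 2) for k, v in cross.items()},
      "| L3 ecdysis: %.2f" % tl.stage_end("L3"))

e = movie.truth.expression
tr = ExpressionTrace("V3", e[e.cell == "V3"].time_h.to_numpy(),
                     e[e.cell == "V3"].intensity.to_numpy())
peaks = detect_stage_peak(tr, tl)
print("V3 expression peaks (h):", peaks["peak_time_h"].round(2).to_dict())
print("peak lead before ecdysis (h):",
      peak_relative_to_event(peaks, tl).round(2).to_dict())
```

prints

```
stage durations (h): [11.17  7.46  7.2   9.68]
body length at hatch / L4 ecdysis (um): 99.9 / 232.4
DTC midline crossings (h): {'DTC_anterior': 25.03, 'DTC_posterior': 25.63} | L3 ecdysis: 26.83
V3 expression peaks (h): {'L1': 11.0, 'L2': 18.33, 'L3': 25.67, 'L4': 35.33}
peak lead before ecdysis (h): {'L1': 1.17, 'L2': 1.3, 'L3': 1.17, 'L4': 1.18}
```

Stage durations scatter around the configured means (11.1, 7.3, 7.1,
10.2 h); the anterior distal tip cell crosses the body midline before the
posterior one, both shortly before the L3 ecdysis; and each larval stage's
expression peak precedes its ecdysis by roughly the planted 1.1 h lag —
noise and 20-min sampling account for the residual spread.

## Command line

```sh
wormlapse simulate --seed 1 --out movie/            # synthetic movie + truth
wormlapse bodylength --annotations movie/annotations.json --out length.csv
wormlapse straighten --image movie/fluorescence.tif \
    --annotations movie/annotations.json --frame 40 --out straight.tif
wormlapse dtc --annotations movie/annotations.json --out-prefix dtc
wormlapse expression --image movie/fluorescence.tif \
    --annotations movie/annotations.json --out-prefix expr
wormlapse lineage-stats --annotations movie/annotations.json --out-prefix lin
```

All commands accept `--config` (YAML overrides), `--log-level`, and exit
non-zero with a message on malformed inputs.

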