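# Methods

This note documents the models, conventions and numerical choices behind
`wormlapse`, and what the synthetic generator does and does not emulate.

## Body-axis model and (s, t) coordinates

The centre line is an **interpolating cubic spline** through the annotated
points (chord-length parameterization, natural end conditions, no
smoothing): manual centre-line clicks are treated as exact, which keeps the
fit reproducible and directly testable against the annotation. The spline
is reparameterized by arc length through dense polyline integration
(500 samples per control segment), so that sampling the curve at equal
s-steps yields equal chord lengths to within 0.1% and the body length *L*
is the integrated curve length.

A camera point maps to body coordinates by nearest-point projection:
*s* minimizes the distance to the curve (coarse minimum over the dense
polyline, then Newton refinement of the orthogonality condition
(p − c(u))·c′(u) = 0), and |t| is that minimal distance. The normal is the
+90° rotation of the tangent, globally flipped once per axis so that the
annotated ventral landmark (gonad in L2–L3, vulva in L3–L4) projects to
t < 0. Conventions chosen where more than one is defensible:

* **Points beyond the head or tail** clamp to s = 0 or s = L with |t| equal
  to the distance to the endpoint, rather than erroring — cells slightly
  beyond the annotated line remain usable.
* **Projection ties** (points near the medial axis of a bend) resolve to
  the smallest s; `projection_ambiguous` warns when several well-separated
  arc lengths are nearly equidistant. With a fitted spline exact ties do
  not occur, so the tie-break matters only in degenerate synthetic cases.
* **Pixels** are 0-based with centres at integer indices; a camera position
  (x, y) in µm lives at image index [y/pixel, x/pixel]. All pixel→µm
  conversion goes through a single `PixelGrid` to avoid half-pixel drift.

Straightening resamples the image onto the (s, t) grid with **bilinear
interpolation** and zero fill outside the field of view; column c is
s = c·pixel and row r is t = (r − height//2)·pixel, so ventral is at the
top and the centre line on the middle row. Note that the map from (s, t)
to the camera plane has area element (1 − t·κ(s)) ds dt, with κ the local
curvature: plain resampling therefore preserves the integrated intensity of
a compact spot only up to a factor ≈ 1/(1 − tκ). Spot intensity is
conserved to better than 2% when |t·κ| ≲ 0.02 — e.g. anywhere within 8 µm
of the axis when the local bend radius exceeds ~400 µm — and this is the
regime the recovery tests exercise. No Jacobian correction is applied,
matching how straightened images are normally read.

## Staging

Ecdysis is an instantaneous annotated event (first appearance of the shed
cuticle). Stage intervals are half-open with the ecdysis belonging to the
next stage, so `assign_stage` is deterministic at boundaries and
piecewise-constant non-decreasing in time. The ecdysis-fraction histogram
normalizes by the total number of animals (not by animals still imaged), so
fraction × N summed over bins recovers the event count exactly.

## Seam-cell lineage statistics

Cells are named founder + side + {a, p} sublineage (`V2L.pp`); division
classes are d = 0 (none), 1 (symmetric: two seam daughters) and
2 (asymmetric: exactly one seam daughter, which must be named). A division
yielding two non-seam daughters is out of vocabulary and rejected. The
stage of a division is the annotator's recorded stage, not a re-derivation
from its time, so molt-boundary divisions follow the annotation.

The error probability P(l, s) pools both body sides into the named lineage
and averages 1 − δ(d_WT, d_M) over **all (mutant animal, shared cell)
comparison pairs** of lineage l and stage s; (l, s) cells shared by no
mutant are reported as missing (NaN), never as zero. Cells created by an
upstream error carry names absent from the reference lineage and drop out
of the shared set automatically, which implements scoring each sub-lineage
only at its first deviation; a cell that fails to divide is itself the
error at that stage, and its never-born reference daughters are likewise
excluded downstream. Marginal stage/lineage means average the defined
entries only.

The built-in reference lineage follows the canonical program — every seam
cell divides asymmetrically in L1, L3 and L4; in L2 the H1, V1–V4 and V6
cells first divide symmetrically and both daughters then divide
asymmetrically — with the posterior daughter taken as seam-fated
throughout. Real anterior/posterior fate polarity varies between founders;
since the statistics compare division classes, not polarity, this
simplification does not affect any computed quantity.

## DTC kinematics

Trajectory smoothing is a centred sliding average with a 1 h window,
uniform weights over in-window samples, truncated (not padded) at the ends.
Velocities are central finite differences on the actual timestamps
(one-sided at the ends), applied to the smoothed series; both operators are
linear, so they commute on interior points of a uniform grid. The outward
A–P sign convention is implemented as sign(s)·ds/dt so the anterior and
posterior DTC share one axis; v_D–V is positive dorsal-ward. The Δs
correction subtracts the mean displacement of anatomical markers seen in
both Z-slices; with no shared marker the correction is skipped with a
warning rather than inventing one. Midline crossings are located on the
smoothed t-series by linear interpolation between the bracketing samples.

## Expression quantification

Kymographs use 100 bins of 1% body length (matching the normalized display
animals of different sizes require) and average pixels with |t| below the
60 µm dorsoventral window. Whole-animal totals subtract a per-frame
background estimated as the median intensity outside the body band, which
makes the total invariant to constant illumination offsets; whether real
totals should be background-subtracted is unsettled, so the subtraction can
be disabled. Nuclear intensities come from an Otsu threshold of the
5 µm × 5 µm ROI; for integer images the histogram uses one bin per grey
level, so the threshold is exactly the between-class-variance maximizer
(verified against exhaustive search). A uniform ROI has no contrast to
segment and raises an error.

The "1 h" Gaussian filter width is interpreted as **σ = 1 h** (not FWHM),
truncated at ±3σ with renormalized edge kernels evaluated on the actual
timestamps. Per-stage peaks are the in-stage argmax of the smoothed trace;
maxima at the first or last in-stage sample are flagged as boundary peaks.
Peak detection is invariant to affine intensity rescaling. Trace
correlation is Pearson's R over exactly-matching time points and is
reported as missing for zero-variance traces.

## Synthetic generator

The generator emulates one larva per movie: a sine-bent midline whose phase
random-walks and whose body translates slightly between frames (animal
movement in the chamber), piecewise-linear body growth from 100 µm at hatch
at stage-dependent rates (2.5/3.5/4.5/5.0 µm h⁻¹ → ~240 µm at the L4
ecdysis), nuclei rendered as 2-D Gaussian spots, a dark body band in the
transmitted channel, and Gaussian read noise. Defaults mirror the measured
biology: stage durations (11.1, 7.3, 7.1, 10.2) h with animal-to-animal
jitter s.d. (0.2, 0.2, 0.3, 0.4) h, seam division-time noise of 0.3 h with
a centre-early/head-and-tail-late offset pattern (V3 −0.4 h, T +0.5 h), a
3 h ventral-to-dorsal DTC turn ending at the L3 ecdysis with the anterior
cell leading by 0.6 h, and one expression pulse per stage (Gaussian, σ =
1 h, SNR 5) peaking 1.1 h before that animal's own ecdysis. Imaging runs
every 20 min from hatch to 2.5 h past the L4 ecdysis, as real sessions
outlast the final molt; full filter support around the last expression peak
needs that margin. Spatial scale is desk-sized by design: 1.5 µm pixels and
256 × 256 frames rather than the 0.16 µm/40× scale of a real chamber; all
geometry is resolution-independent, so nothing in the analysis depends on
this choice.

Annotated division times snap to the first frame at or after the true
event, as an annotator scoring "first appearance of two daughter nuclei"
would, so annotation-derived times sit within one frame of truth by
construction. The multi-Z acquisition of a real microscope is emulated only
as a planted A–P offset between the two Z-slices carrying markers and
DTCs, which is exactly what the Δs correction consumes. Not emulated: 3-D
optics (PSF, scattering, the side-dependent visibility of seam cells),
photobleaching, bacterial food, or lineage-error mutants (error trees are
constructed directly in tests). Passing tests therefore demonstrate the
correctness of the measurement chain on movies with known truth — not
robustness to segmentation-hostile real-image artefacts, which annotations
sidestep by design.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use: 5 random worm-like axes ×
100 points against a 10⁵-sample brute-force projection oracle (0.05 µm);
round trips to 1e−6 µm wherever |t| is below the local bend radius; 100
randomized toy lineages (≤3 generations, ≤5 animals) against an exhaustive
enumeration oracle (exact); 200-seed Monte-Carlo peak recovery at SNR 5
(≥95% within ±20 min); a 20-animal cohort for timing statistics; and one
fully rendered ~115-frame movie for end-to-end recovery (division times
within one frame, body length within 1%, pooled trace correlation within
0.05 of the analytic attenuation var_s/(var_s + var_n)). These sizes keep a
full run of suite plus acceptance script under a few minutes on one CPU.

## Known limitations

* The body axis is planar per frame; Z-membership of a cell never bends the
  axis, matching the annotate-in-projection workflow.
* Straightening applies no curvature Jacobian, so intensity integrals over
  strongly bent, off-axis regions are biased by ≈ t·κ (see above).
* P(l, s) weights every comparison pair equally; an animal contributing
  more shared cells contributes more weight. Per-animal-first averaging
  would differ when cell counts are unbalanced.
* `trace_correlation` matches timestamps exactly (to 1e−9 h); traces on
  different clocks must be resampled first.
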