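# Methods

This note documents the models, parameter choices, and numerical decisions in
`na_dynamics`, and what the synthetic-data experiments do and do not show.

## Substrate mechanics and traction reconstruction

The substrate is an isotropic, linear-elastic half-space of infinite depth
(valid for gels much thicker than the bead displacement scale). Tangential
surface tractions only; normal (z) forces are out of scope. The surface
Green's function is the Boussinesq–Cerruti tangential solution; with
`E = 5000 Pa` and `ν = 0.5` (incompressible silicone; `ν` is configurable —
the value is a package default, not a measured one) a 300 Pa patch of 1 µm
radius displaces nearby beads by ~0.15 µm ≈ 2 px at 80 nm pixels.

The forward map is assembled on a square mesh whose width is
`w = sqrt(1/bead density)` — one cell per average bead area, the resolution
the data can support. A unit force on a cell is distributed uniformly over it;
the matrix entry integrates the Green's function over the cell by 4×4 subcell
quadrature, with the subcell self-term regularized at half the subcell width.
The quadrature leaves the far field exact and keeps the near-field response
consistent with how the generator discretizes its traction patches; a single
center-point evaluation with a w/2 cutoff was measurably inconsistent with a
smooth planted patch and produced spurious oscillating forces.

Unknowns are nodal forces in nN; reported tractions are force / cell area
(1 nN/µm² = 1 kPa). Inversion is FISTA (accelerated proximal gradient with
soft thresholding), step = 1/L with L from 50 power iterations, stopping at
relative change 1e-6 or 10⁴ iterations (non-convergence warns and returns the
iterate; at extreme λ values on the L-curve grid this is expected and
harmless). λ is selected at the maximum finite-difference curvature of
(log‖Mf−u‖, log‖f‖₁) over a ≥10-point log-spaced grid, solved sparse-to-dense
with warm starts; a monotone-curvature (degenerate) L-curve falls back to the
grid midpoint with a warning.

PIV: beads are detected on the reference image as local maxima of a lightly
smoothed image; each bead's template (default 19 px) is matched by normalized
cross-correlation within ±max-displacement; the peak is refined by a 3-point
Gaussian (fallback parabolic) fit per axis, ties broken toward smaller
displacement. Identity tracking is zero only up to the subpixel-fit
resolution (~0.05 px) because neighboring beads skew the 3-point fit.
Outliers are flagged (never modified) by a normalized-median test against the
8 nearest neighbors with threshold 2 and stabilizer 0.1 px; fields with too
few beads pass through unchanged with a warning.

Strain energy is `½ Σ u·T w²` over mesh nodes inside the cell mask, with bead
displacements linearly interpolated onto the mesh; Pa·µm·µm² = 1e-18 J, and
the result is reported in fJ.

## Detection and segmentation

Point sources: LoG response at the PSF scale (σ = 2.1 px ≈ 180 nm), local
maxima above median + 5 robust (MAD) sd of the response, then per-candidate
isotropic Gaussian fits (amplitude, position, background; σ free only in PSF
validation mode). A candidate is accepted when its fitted amplitude exceeds
z₁₋α standard errors (from the local fit residual) above zero, α = 0.05. The
threshold constant 5 was calibrated once on noise-only and planted-spot
frames to give ≥95% recall and precision at peak SNR 5 with ~0 false
positives per noise frame, then frozen.

FC/FA segmentation: Gaussian denoise (σ 1 px), background subtraction by
morphological opening (disk radius 10 px), threshold = arithmetic mean of
Otsu's and Rosin's thresholds (Rosin implemented via the triangle
construction; the combination rule is selectable mean/min/max). Components
with area > 0.2 µm² are kept and labelled FA if the fitted ellipse major axis
exceeds 2 µm, else FC. Both thresholds are intensity-scale covariant, so
segmentation is invariant to positive rescaling.

## Edge geometry

Cell masks: Otsu on log intensity, hole filling, largest component. Edge
velocity at a boundary point is the frame-to-frame difference of the signed
distance-to-boundary transform (positive inside), divided by the frame
interval; an expanding mask reads positive everywhere. The signed distance is
measured to the boundary pixel set, so boundary pixels are exactly 0.
This distance-transform approach is a deterministic stand-in for the original
boundary-tracking machinery; it is sufficient for the features that consume
it.

## Tracking

Greedy cost-capped nearest-neighbor linking (cap 5 px/frame default), gaps up
to 2 frames closed by linear interpolation, ties toward the lower track id.
This is a deliberate simplification of full assignment-problem trackers: on
the well-separated trajectories the generator plants (and that NA densities
at the stated detection scale produce), greedy and optimal assignment
coincide, and the 2×2 swap case is covered by a brute-force test. No
merge/split handling, no motion model.

## Features and classification

22 features per track: f1 lifetime ((n−1)·Δt), f2–f9 amplitude statistics and
least-squares slopes over 10-s windows, f10–f17 speeds/distances relative to
the moving edge (signed edge-normal velocity positive toward the protruding
edge), f18–f21 FC/FA overlap, f22 born-within-1-µm-of-edge. Single-frame
tracks impute spatial features to 0 and carry a validity flag. The 9/13
intensity/spatial split and the specific list reconstruct the established
feature set for this assay family from its described examples; individual
definitions (windows, conventions) are this package's own and documented in
`features.py`.

Classifier: degree-3 polynomial SVM, `coef0 = 1` (the usual inhomogeneous
"cubic SVM"; the homogeneous kernel lacks lower-order terms and fails even
cleanly separable data near the origin), C = 1, one-vs-one, standardized
features, seeded stratified 5-fold validation. Labels: conservative
rule-based auto-labeling (high precision, deliberately incomplete) plus
manual overrides through the same `LabelSet` API; training requires ≥10
labels per class; classes are balanced to round(mean count) by seeded
over/under-sampling.

## Event analysis

Onset (FII/FTI) rule: first run of ≥3 frames above background mean + 2 sd,
backtracked to the frame after the last value ≤ mean + 0.5 sd. The 0.5-sd
backtrack floor matters: backtracking to the strict mean walks through
pre-onset noise runs and is early-biased on steps, while stopping at the
2-sd crossing is late-biased on slow ramps by ~2 sd/slope. With the floor,
median onset error is ≤1 frame on ramps reaching SNR 5 in 10 s, and the
residual bias is common-mode between the intensity and traction channels
(equal rise times in sd units), so it cancels in the lag. Assembly and
traction growth rates are least-squares slopes over 10 s / 120 s windows
aligned at detection (track birth); the FII-aligned variant in
`annotate_events` inherits onset uncertainty and is slightly low-biased.

Group statistics: two-sided Mann–Whitney U (tie-corrected; all-tied input
returns p = 1 with a warning) and a one-sample KS test against a normal with
fitted mean/sd. Cohort averages align tracks at birth within lifetime bins.

## Synthetic generator

The generator is first-class, tested code; its defaults define the study
conditions. Nine archetypes plant the class structure (values in
`synthetic.ARCHETYPES`): lifetimes G1 390±90 s, G2 1100±150 s (maturing,
>15 min), G3 80±30 s, G9 1–3 frames; amplitudes rise linearly at the
archetype's assembly rate over `RISE_S = 20 s` to a plateau of rate × rise;
G2 vinculin assembly rate is exactly 5× the G1 value; G2 slides rearward (−0.5 µm/min
along the edge normal) and always matures to FC with 32% reaching FA; G3
rides the protrusion (+1 µm/min) with the lowest NA amplitude and zero
traction. FA classes G6/G7/G8 are stable/growing/sliding patches rendered
with a 1.2 µm major-axis sd. The timing presets plant intensity-before-
traction leads of 18/8/4 s (G1 talin/vinculin/paxillin) and 4 s (G2), and an
"r8vvv" variant in which G1 vinculin trails talin by 17 s; all leads get 2-s
Gaussian jitter, so recovery targets are medians.

Event traces ramp both channels over the same 20-s rise at the same SNR
(noise sd = plateau/SNR per channel) on a 60-s background pre-window — the
condition under which onset-detection bias cancels in the lag. The
cell edge is a sinusoidal moving front (amplitude 1 µm, period 120 s); it
provides exact distance/velocity geometry for feature tests and rendered
masks for the image path. Bead fields are dart-thrown uniform points with a
minimum spacing (default density 1.54/µm², the value the substrate protocol
reports — printed there per µm, read here as per µm² consistent with the
0.42 µm mean spacing). Camera noise is Poisson shot noise (gain 1) plus
Gaussian read noise; SNR is peak amplitude / background sd.

What the generator does **not** emulate: photobleaching, drift, illumination
fields, 3D PSF optics, merging/splitting adhesions, bead z-motion, nonlinear
or finite-thickness substrates. Passing tests therefore demonstrate correct
recovery of the planted model under idealized imaging, not robustness to
every artifact of real microscopy.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen as the package's
default demonstration sizes: 20×20 µm TFM fields (~400 beads, 400 mesh
nodes), two 270-track movies for classification, 200 traces per timing
preset, 100 spots for PSF validation. The classifier's hold-out accuracy on
these synthetic movies (≈98–100%) exceeds what heterogeneous real data yield,
because archetypes are well separated by construction; the acceptance bound
is the conservative ≥70%.

## Known limitations

- The L-curve corner on noise-free data is weakly defined (residual falls
  monotonically); the degenerate-corner fallback warns and returns the grid
  midpoint.
- Greedy linking can mis-assign at densities far above the planted regime.
- Auto-label rules are tuned to the archetype presets; on real data they are
  a starting point for the human-in-the-loop workflow, not a classifier.
- The FII-aligned rate estimator is ~15–20% low-biased at SNR 5 (onset
  uncertainty admits pre-onset frames into the window); ratios between
  conditions are unaffected since the bias is common-mode.
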