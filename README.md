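# na-dynamics

Analysis of nascent adhesion (NA) dynamics in migrating cells: high-resolution
traction force microscopy (TFM), detection and tracking of diffraction-limited
adhesions, nine-class trajectory classification, and event-based timing of
protein recruitment versus force transmission.

Nascent adhesions are sub-resolution (< 0.5 µm) integrin clusters that form
under the protruding lamellipodium; a small subset matures into focal contacts
(FCs, > 0.5 µm) and focal adhesions (FAs, > 2 µm) while the rest turn over.
This package implements the computational side of that biology for two-channel
TIRF movies (adhesion marker + fiducial beads on a deformable substrate), and
ships a synthetic-data generator that plants known ground truth — trajectories
per behavioral class, recruitment/traction onset lags, traction patches — so
every stage is testable end to end without any external data.

## What it computes

**Traction reconstruction.** Bead displacements `u` are measured by per-bead
normalized cross-correlation (template 17–21 px, subpixel 3-point Gaussian
peak fit) between the deformed and relaxed-substrate bead images. The
substrate is an elastic half-space; a tangential point force `F` at the
surface displaces the surface at in-plane distance `r` by the
Boussinesq–Cerruti solution

    u_i(r) = (1 + ν) / (π E r) [ (1 − ν) δ_ij + ν r_i r_j / r² ] F_j

with Young's modulus `E` (default 5 kPa) and Poisson ratio `ν` (0.5).
Nodal forces on a square mesh (width = average area per bead) are recovered by
sparsity-preserving L1-regularized inversion

    min_f ‖M f − u‖₂² + λ ‖f‖₁

solved by FISTA, with `λ` chosen automatically at the maximum-curvature corner
of the L-curve. Strain energy is `½ ∫ u·T dA` over the segmented cell, in fJ.

**Detection, segmentation, tracking.** NAs are detected as point sources
(Laplacian-of-Gaussian filtering, local maxima, isotropic Gaussian fits of
sd 2.1 px with an amplitude-significance test at α = 0.05); FCs/FAs are
segmented at the mean of Otsu's and Rosin's thresholds and classified by
ellipse major-axis length. Detections are linked into trajectories by greedy
cost-capped nearest-neighbor assignment with gap closing.

**Classification.** Each trajectory yields 22 features (9 from the intensity
trace, 13 spatial: speeds, signed edge-normal velocity, distances to the
moving cell edge, FC/FA overlap). A cubic-kernel SVM over standardized
features, trained on rule-based auto-labels (optionally amended manually) and
balanced to the mean class count, assigns one of nine classes G1–G9:
five NA behaviors (G1 non-maturing, G2 maturing, G3 protrusion-riding,
G4 edge-distal, G5 FC-contacting), three FA behaviors (G6 stable, G7 growing,
G8 sliding/disassembling), and G9 noise.

**Event timing.** Per track, the first intensity increase (FII) and first
traction increase (FTI) are the first run of ≥ 3 frames above the local
background mean + 2 sd, backtracked to the last sub-background frame. The lag
`t_FII − t_FTI` measures how long a protein is present before force
transmission; assembly and traction growth rates are least-squares slopes over
fixed windows after detection.

## Worked example

Generate a synthetic scenario (108 tracks, 12 per class) and run the full
pipeline:

```sh
na-dynamics run --generate --seed 1 --out results/run1 --tracks-per-class 12
```

prints

```json
{
 "seed": 1,
 "preset": "wildtype",
 "n_tracks": 108,
 "svm_validation_accuracy": 1.0,
 "median_lag_s": {"G1": -8.0, "G2": -4.0},
 "maturation": {"na_to_fc_pct": 33.3, "na_to_fa_pct": 6.9, "fc_to_fa_pct": 68.3}
}
```

The median lags say that on the wild-type preset, vinculin appears 8 s before
the first traction rise in non-maturing (G1) NAs but only 4 s before it in
maturing (G2) NAs — the planted recruitment order, recovered by the event
detector from noisy traces (negative lag = protein precedes force). The
maturation percentages count NA-born tracks whose positions enter FC/FA
segmentations. Stage outputs (features, class predictions, lag tables, truth
sidecars) are written under `results/run1/`.

The TFM stage can be run alone on a rendered movie:

```sh
na-dynamics generate --seed 3 --out scenario/
na-dynamics tfm --deformed scenario/beads.tif --reference scenario/reference.tif \
    --E 5000 --template 19 --max-disp 20 --out tractions/
```

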