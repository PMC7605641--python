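# Methods

## Pipeline model and assumptions

The package treats an awake-rodent rsfMRI scan as a 4D volume whose frames
differ by (i) rigid head motion, (ii) slowly varying neural (BOLD) signal
in the 0.01–0.1 Hz band, (iii) structured non-neural artefacts
(vascular/CSF pulsation, boundary effects, acquisition patterns), and
(iv) thermal noise.  Preprocessing removes (i), (iii) and the
physiological part of (iv) while preserving (ii); the analysis layer then
estimates inter-regional connectivity from what remains.

Template alignment and deformable normalisation are deliberately out of
scope: inputs are assumed template-aligned (true by construction for
phantoms), and both steps are exposed as a pluggable external hook with an
identity default.

## Motion

**FD.**  Rigid parameters of each frame are estimated relative to the
first frame; consecutive parameter differences are combined as
`FD = Σ|Δt| + r·Σ|Δangle|` with `r = 5 mm`.  "Neighbour frames" of an
exceedance are both temporal neighbours (configurable to one side);
spin-history effects contaminate both directions.  Scrubbing runs before
motion correction; the sidecar FD is the pre-correction FD of the full
scan.

**Registration.**  Levenberg–Marquardt least squares on the intensity
difference over the six rigid parameters (rotations about the image
centre, Euler order Rz·Ry·Rx), warm-started from the previous frame
during motion correction and from the centre-of-mass translation
otherwise; a cold start first runs a short Powell capture sweep.  Two
design points matter on small grids:

* *Out-of-field handling.*  Residual entries whose sample position leaves
  the FOV are excluded (via a resampled ones-volume), and the outermost
  FOV shell never enters the residual.  Zero-filling instead would
  penalise any candidate that shifts mask voxels across the boundary and
  bias the optimum toward the identity; including the outer shell makes
  the objective discontinuous exactly at integer alignments.
* *Regularisation.*  `estimate_motion` adds a weak Tikhonov prior on the
  parameters (rotations especially).  On a 10-slice slab the rotation
  axes are weakly identifiable and an unpenalised fit drifts along them;
  the prior only matters where the data carry little information.

Measured on the desk-scale phantom (24–32 voxels in-plane, 10 slices,
thermal noise σ = 2% of tissue intensity), the per-frame registration
noise floor is ~0.01 mm in-plane, ~0.05 mm through-plane and ~0.001–0.005
rad; the FD series inherits roughly twice that.  Through-plane precision
is intrinsically limited by slice thickness relative to brain height.
Tests and phantom configurations account for this floor (e.g. the
end-to-end phantom uses an FD threshold of 0.3 mm); the pipeline defaults
remain the standard values (0.2 mm, first 10 frames, 90% retention).

## Denoising

**Spatial ICA.**  Frames-by-voxels data are voxelwise demeaned and
decomposed with FastICA after PCA whitening; spatial maps are the
sources, time courses the mixing columns.  Maps are z-scored over brain
voxels and sign-fixed to positive skewness; results are deterministic
under a fixed seed.  Component count: 50 on full-size scans, smaller on
phantoms (always below the frame count).

**Classification.**  The qualitative rodent-adapted criteria are given
explicit thresholds so labels are reproducible: the spatial criterion
fires when (WM/CSF + boundary) overlap of the |z| > 2 voxels exceeds 0.5
while grey-matter overlap stays below 0.5 (boundary-shell voxels do not
count as grey matter here — the criterion opposes GM against
WM/CSF/boundary); the jump criterion fires above a maximum standardised
first-difference of 6; the spectral criterion fires when the 0.01–0.1 Hz
fraction of periodogram power falls below 0.5, the > 0.2 Hz fraction
exceeds 0.5, or spectral flatness exceeds 0.8.  All thresholds are
configurable; fired features are recorded per component for audit.
"Confident" features (susceptibility zones, acquisition banding) are
optional user-supplied detectors, disabled by default on phantoms.

**CompCor.**  WM/CSF voxel time courses are variance-normalised before
PCA so the i.i.d.-normal Monte-Carlo null is the matched reference;
variance explained is eigenvalue/trace.  Because variance explained is
decreasing in component index, the selected set is always a prefix of the
variance ordering.  The null distribution depends only on (T, V, n_mc),
so callers may pass a precomputed null (`null_varexp`) when running many
scans of identical size.

**Soft cleaning** operates on the unsmoothed retained frames, with IC
maps from the smoothed data regressed against the unsmoothed frames to
obtain the time courses used in cleaning.  The nuisance design (intercept
+ motion + CompCor) is regressed from both data and IC time courses; the
joint regression of all components then yields the unique noise
contribution to subtract.  All regressions run on the retained-frame axis
only; scrubbed frames are never interpolated.

## Filters

Smoothing is isotropic in millimetres (per-axis sigma = FWHM/(voxel ·
2√(2 ln 2))), reflective boundaries.  The band-pass is applied
forward–backward (zero phase, preserving FC timing), so effective
attenuation is the squared single-pass Butterworth response; retained
frames are treated as temporally contiguous, an approximation documented
here.  Start-up transients extend ~150 frames at the 0.01 Hz band edge;
frequency-response checks therefore measure the steady-state mid-section.

## Group analyses

Scans are truncated to common 540-frame segments (two disjoint segments
from ≥ 1080-frame scans) so every segment contributes equal degrees of
freedom; phantom configurations scale this down proportionally.  Group
inference computes per-entry one-sample t statistics on per-subject mean
Fisher-z values: with one scan per subject this *is* the classical
one-sample t, and for balanced designs it equals the random-intercept
mixed-model test.  A per-entry REML mixed model (statsmodels) is
available (`method="reml"`), but the subject-mean estimator is the
default: it is deterministic, exact in the balanced case, and fast enough
to sit inside the permutation loop.  FWER control shuffles ROI labels
independently per scan and thresholds at the 95th percentile of the
max-t null.  Voxelwise seed-map inference uses sign-flipping of
per-subject maps instead (ROI-label shuffling has no voxel analogue).

Other choices: FC–SC Jaccard significance uses Erdős–Rényi rewiring at
matched density; Ward linkage runs on d = (max t − t) with the diagonal
excluded; the dendrogram cut (count or height) is always explicit;
reproducibility regresses Euclidean ROI distance out of both matrices
before correlating; the seed-specificity threshold is Fisher z = 0.1;
the sSNR reference frame is the 10th (index 9, 0-based), with the noise
pool from two 5×5 corner squares per slice; capped t entries (zero
residual variance) are reported at a flagged cap, never silently.

## Phantom generator

The phantom emulates the geometry of a rodent EPI acquisition (64×64×20,
TR 1 s at full size; 32×32×10×300 desk scale by default, voxels
0.5×0.5×1 mm): an anisotropic ellipsoidal brain (semi-axes 0.40/0.34/0.33
of the grid) with an anterior-shifted WM shell and CSF ventricle — the
asymmetry makes rigid rotations identifiable — plus multiplicative
smooth anatomical texture (15%, 1.5-voxel scale) and partial-volume
softening (Gaussian 1.5 voxels).  The brain leaves a margin inside the
FOV; scipy's resampling zero-fills whole boundary slices for any
sub-voxel shift, and a brain touching the FOV edge would corrupt both
generation and registration.

Planted content: networks are groups of atlas sectors sharing a
unit-variance 0.01–0.1 Hz Gaussian time course (amplitude 3, i.e. 3% of
GM baseline — at the upper end of BOLD fluctuation amplitudes so planted
structure is detectable at desk-scale T); artefact components pair
compact spatial patterns (quarter boundary ring, half-WM blob, slice
banding) with time courses that violate the signal profile (> 0.2 Hz
noise, slow drift, 8-σ spikes); motion is i.i.d. rigid jitter plus
optional displacement spikes, applied by resampling each frame before
noise is added; thermal noise is i.i.d. Gaussian (σ = 2 by default
against a GM baseline of 100).

The default atlas is 12 angular sectors of grey matter.  Default networks
occupy four contiguous double-wedges separated by quiet sectors
(`(1,2), (4,5), (7,8), (10,11)`): tiling all of GM with equal-amplitude
networks makes their *sum* a structured sparse pattern of its own, and
adjacent supports blend under smoothing — both measurably hurt ICA
separability.  Realistic jitter uses σ ≈ 0.015 mm, which reproduces the
~0.05 mm mean FD regime of restrained awake rats.

**Motion-parameter leakage.**  Intensity-based realignment attributes
part of any structured signal fluctuation to apparent motion, so the
estimated motion parameters contain a component proportional to the
planted time courses; regressing them out then removes planted signal.
On a desk-scale phantom with only a handful of temporal sources this
coupling is drastic (motion columns can explain most of a network time
course), whereas real data dilute it across thousands of fluctuation
modes.  Two generator features control it: network supports are kept off
the brain-boundary shell (`network_interior_erosion`, default one
erosion step), because fluctuations on the high-gradient outer shell
couple most strongly into the rigid fit; and end-to-end configurations
use two erosion steps.  This also mirrors real data, where BOLD signal
is partial-volume diluted at the brain surface.

Group datasets spawn per-scan seeds from one `SeedSequence`; subject j
scales all network amplitudes by `1 + σ_subj·z_j` (z clipped at ±2),
giving the random-effect structure the group model assumes.  The truth
object (maps, time courses, motion schedule, FD, masks, atlas, binary SC)
suffices to score every stage.

What the phantom does not model: MR physics (susceptibility, ghosting,
slice-timing), physiological waveforms, spatially correlated scanner
noise, and deformable anatomy differences between subjects.  Passing
tests therefore demonstrate algorithmic correctness and calibration under
the stated generative model, not performance on real acquisitions.

## Problem sizes

Unit tests run on 24–32-voxel grids with 100–300 frames.  The end-to-end
check uses 20 subjects × 140 frames at 24×24×10 with two planted
three-ROI modules; the acceptance script uses 10 subjects for the same
end-to-end configuration and 25–1000 replicates per calibration, sizes
chosen to keep a full run in the minutes range on one CPU.

## Known limitations

* Through-plane (z) translation precision is bounded by slice thickness;
  FD series on thin-slab phantoms carry a noise floor of ~0.1 mm.
* The subject-mean group estimator equals the mixed model only for
  balanced designs; strongly unbalanced scan counts should use
  `method="reml"`.
* ICA separability degrades when planted sources are adjacent, tile the
  brain, or share amplitudes; the classifier is robust to moderate
  mixing but map-level recovery thresholds assume separable layouts.
* Scrubbed series are filtered as if contiguous; for heavily scrubbed
  scans the effective band edges blur.
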