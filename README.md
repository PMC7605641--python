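# ratfc

Preprocessing and functional-connectivity analysis for awake-rodent
resting-state fMRI, with a ground-truth phantom generator that makes every
stage testable without real data.

Awake-rat rsfMRI avoids anaesthesia confounds but pays for it with head
motion and non-neural artefacts.  `ratfc` implements the full denoising
chain used for such data and the standard group analyses on top of it:

1. **Motion scrubbing** by framewise displacement,
   `FD_i = |Δx_i| + |Δy_i| + |Δz_i| + r·(|Δα_i| + |Δβ_i| + |Δγ_i|)` with
   `r = 5 mm` (cortex-to-head-centre distance in the rat); frames with
   `FD > 0.2 mm` are dropped together with both neighbours, plus the first
   10 frames; scans keeping < 90% of frames are excluded.
2. **Rigid motion correction** to the first retained frame (in-house
   intensity-based registration, masked by a dilated brain mask).
3. **Per-scan spatial ICA** (FastICA after PCA reduction, 50 components on
   full-size data) with a rodent-adapted noise-component rule: a component
   is noise if it shows one "confident" feature or at least two of three
   "applicable" features — WM/CSF/boundary-dominated map, sudden time-course
   jumps, or a spectrum that is flat or dominated by very low/high frequency.
4. **Monte-Carlo CompCor**: principal components of WM+CSF signals whose
   variance explained beats the first PC of 1000 simulated i.i.d.-normal
   datasets of the same size (p < 0.05) become nuisance regressors.
5. **Soft cleaning**: after regressing motion and CompCor columns from both
   data and IC time courses, only the *unique* contribution of the noise
   components is subtracted (`Y_clean = Y_m − ICA_m(noise)·β(noise)` with
   `β = pinv(ICA_m)·Y_m` over all components jointly), preserving variance
   shared with signal components.
6. **Smoothing and filtering**: Gaussian FWHM 1 mm, zero-phase 4th-order
   Butterworth band-pass 0.01–0.1 Hz.
7. **Group analyses**: Fisher-z ROI connectivity from 540-frame segments,
   group t statistics with subject as the random unit, max-t permutation
   FWER control, seed maps, FC-vs-distance, FC/SC Jaccard overlap,
   split-half and leave-one-out reproducibility, seed-specificity
   categories, group ICA with Ward-linkage module clustering, and
   spatial/temporal SNR maps.

## Worked example

Generate a synthetic group, preprocess it, and compute group FC:

```bash
ratfc phantom work/ds --n-subjects 4 --nt 300 --seed 7
ratfc preprocess work/ds work/deriv --seed 7
ratfc analyze work/ds work/deriv work/fc
```

The `analyze` step prints:

```
significant-FC density: 12.12% (t_crit=10.609, 4 segments)
```

meaning 12.12% of the off-diagonal ROI pairs exceeded the max-t permutation
threshold (here t = 10.6) at family-wise error 0.05 — on this phantom those
pairs are the planted within-network connections.  Per-scan sidecar JSONs
record the FD series, scrubbed fraction, noise-IC indices and CompCor
p-values; `work/fc/group_t.csv` and `group_sig.csv` hold the group t matrix
and its significance mask.

The same operations are available as library calls (`ratfc.motion.scrub`,
`ratfc.denoise.compcor`, `ratfc.analysis.permutation_fwer`, ...), which is
how the test suite drives them.

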