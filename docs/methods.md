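# Methods

This note documents the models and procedures implemented in `comet`, the
choices made where the underlying definitions are open, and what the
synthetic phantoms do and do not establish.

## The rotation and its guarantees

Given an activity map `a` and a supply map `s` on one gray-matter mask, both
are z-scored within the mask using the population standard deviation
(divisor *n*, recorded as `sd_divisor: "n"` in the map metadata) so that the
standardized maps have mean 0 and variance exactly 1 on the given voxel set.
The rotation

```
[rPWR]   [ cos π/4  sin π/4] [z(a)]
[rCST] = [−sin π/4  cos π/4] [z(s)]
```

is implemented in Cartesian form; the polar form R·cos(θ−π/4), R·sin(θ−π/4)
is kept as an independent cross-check and asserted to agree to < 1e−10.
Because the rotation is linear and orthogonal, four identities hold for any
valid input and are enforced in tests: zero means, zero cross-covariance,
the variance split 1 ± r, and per-voxel isometry. The PCA statement — for
r > 0 the first principal axis of the standardized pair is (1, 1)/√2 — is
exact for the empirical correlation matrix; the deviation is computed with
atan2 of the cross/dot products of the axes (arccos of a near-unit dot
product would amplify rounding to ~1e−8).

Two different quadrant constructions coexist and must not be conflated:

* **Energy states** split the *rotated* (rPWR, rCST) plane at its zero
  means, each quadrant gridded 5×5 over |value| ∈ [0, 5] with a per-quadrant
  overflow count (the binning geometry is a package choice; [0, 5] covers
  > 99.99 % of standardized mass and is configurable). Since rPWR and rCST
  are uncorrelated, an elliptically symmetric input puts ≈ 25 % in each
  quadrant; deviations from that are distributional findings.
* **Power dominance** counts voxels concordant in the *source* plane
  (z(a)·z(s) > 0, equivalently |rPWR| > |rCST|). For a bivariate-normal pair
  this share is ½ + arcsin(r)/π ≈ 64.5 % at r = 0.44, and it is the correct
  formalization of "most voxels lie in the high- and low-power quadrants" of
  an activity–supply scatter.

Moments are reported with the moment (biased) estimators: skewness
m₃/m₂^{3/2} and Pearson kurtosis m₄/m₂² (normal → 3); the convention is
deliberate and recorded because "kurtosis" is ambiguous across packages.

## lFCD

For each in-mask seed, the local functional connectivity cluster is grown
from the seed by repeatedly adding any in-mask voxel that is lattice-adjacent
to the current cluster and whose Pearson correlation *with the seed* exceeds
the threshold; lFCD(seed) = cluster size − 1. The grown set equals the
connected component containing the seed of {seed} ∪ {v : corr(seed, v) >
threshold}, which makes the result provably independent of scan order; the
test suite checks it against an independent connected-component-labeling
oracle on random 3×3×3 phantoms, exhaustively over thresholds {0.4, 0.6} and
adjacencies {6, 18, 26}.

Choices where the definition is open:

* **Adjacency** defaults to 18 (faces + edges), configurable to 6 or 26; the
  monotonicity lFCD₂₆ ≥ lFCD₁₈ ≥ lFCD₆ and lFCD₀.₄ ≥ lFCD₀.₆ is asserted.
* **Correlation is signed**: anti-correlated voxels never join.
* **Zero-variance voxels** have correlation defined as 0 and can neither
  join a cluster nor grow one (their lFCD is 0).
* **log(lFCD)** uses the natural log with zero degrees floored at one,
  log(max(lFCD, 1)), so the support stays non-negative; the base is
  immaterial after standardization but fixed for reproducibility.
* **Multi-session data** are mapped per run and averaged voxelwise *after*
  the log transform.

Edge voxels of the lattice have fewer neighbors and thus a geometric
handicap in lFCD; on real masked data the same applies to the gray-matter
boundary. Comparisons between voxel populations should be matched for this
(the null-phantom test restricts its background sample to interior voxels
for exactly this reason).

## fALFF

fALFF is the ratio of summed Fourier amplitudes in [0.01, 0.1] Hz to the
sum over (0, Nyquist], computed on the full-spectrum series (the package
refuses band-passed input) after demeaning. A Hann taper is applied before
the FFT: rectangular-window sidelobes otherwise leak a substantial share
(~16 % at 512 frames) of a non-bin-centered narrowband signal's amplitude
out of band, while the taper leaves the flat-spectrum baseline — white noise
scores ≈ band width / Nyquist ≈ 0.27 at TR = 1.5 s — unchanged. Voxels with
(numerically) zero temporal variance get fALFF 0 with a warning.

## Preprocessing

The pipeline order is fixed and logged in each series' history: band-pass
(4th-order Butterworth, applied forward–backward for zero phase) → scrub →
motion regression.

* **DVARS** is the frame-to-frame RMS signal change over in-mask voxels as a
  percent of the whole-series in-mask mean; frame 0 is 0 by convention. The
  normalization by the *whole-series* mean (not per-frame) is a declared
  reading of an under-specified convention.
* **FD** is the sum of absolute parameter derivatives with rotations
  converted on a 50 mm sphere (field convention); frame 0 is 0.
* **Scrubbing** censors frames with DVARS > 0.5 % or FD > 0.5 mm, exactly
  the flagged frames (no neighbor augmentation), preserving frame order; it
  errors below `min_frames` (default 50) and warns above 10 % censoring.
  DVARS used for censoring is computed on the unfiltered series, since the
  filter removes the mean signal the percent normalization needs.
* **Motion regression** removes an OLS fit on [intercept | regressors] per
  voxel. In the pipeline the motion parameters are band-pass filtered with
  the same filter as the data before regression — unfiltered regressors
  cannot cancel motion-locked artifact that the filter has reshaped, and for
  step-like displacements the mismatch is catastrophic (the 0.01 Hz
  high-pass turns a step into a long shared transient).

Filtering before censoring is a known leakage caveat of this order; it is
retained deliberately and mitigated by the filtered-regressor step above.

## Network segregation

NSI_i = ABND_i / AWND_i with centers of mass, within- and between-network
distances as plain Euclidean means in the raw units of the 2D embedding (no
re-standardization across subjects). NSI is invariant to rigid motions and
uniform scaling of the whole point cloud, and scales as 1/s when
within-network deviations shrink by s — all asserted. Networks with a single
subject point, or with coincident points (AWND = 0), raise errors rather
than returning infinities. The Wilcoxon signed-rank comparison of NSI
between two embeddings is exposed as a thin convenience over scipy.

A subtlety the cohort phantom makes explicit: the rotation itself is rigid
and cannot change NSI. The segregation gain of the rPWR–rCST embedding over
the raw (activity, supply) embedding comes from the *per-subject
standardization*, which removes subject-level global shifts and gains
(scanner scaling, global metabolic level) that inflate within-network spread
in raw units.

## Segmentation

k-means (Lloyd, k-means++ initialization, up to 1000 iterations) runs
`n_repeats = 100` times from seeds drawn from one master seed; the reported
labeling is the best-inertia run after canonicalizing cluster ids by
lexicographic centroid order, and stability is the fraction of runs whose
canonical labeling matches it exactly. Stability 1.0 therefore certifies a
basin-dominant structure; diffuse clouds legitimately score near 0. Fixed
seed ⇒ bit-identical results. The intended input is the group-average
rPWR/rCST maps; per-subject use is possible but is a different analysis.

## Synthetic phantoms

* `make_coupled_pair` builds two Gaussian-smoothed random fields (default
  2 voxels FWHM, giving realistic spatial autocorrelation) and mixes the
  second from the first with weights (r, √(1−r²)) after empirically
  residualizing and re-standardizing, so the realized in-mask correlation
  equals the target exactly (not merely in expectation). Maps are returned
  on raw-looking scales (means/SDs mimicking log(lFCD) and CMRglc units)
  which downstream standardization removes.
* `make_bold_phantom` (default 20×20×12, 400 frames, TR 1.5 s) plants
  spherical hubs sharing a band-limited (0.01–0.1 Hz) latent signal of
  amplitude 2 noise-SDs on a baseline of 1000, plus i.i.d. voxel noise and
  small motion jitter. Spikes are *persistent steps* in global intensity
  (1.5 % of baseline) and x-translation (0.8 mm): a one-frame impulse would
  trip the frame-difference metrics at the spike frame and the frame after
  it, whereas a step is flagged at exactly the planted frame.
* `make_cohort` partitions the volume into equal slabs per network, plants
  per-network (activity, supply) offsets (default: 10 networks on a unit
  circle), and adds per-subject voxel noise plus optional global shift/gain
  nuisance.

What the phantoms do **not** emulate: hemodynamic response functions,
physiological (cardiac/respiratory) noise, PET count statistics and partial
volume effects, anatomically shaped masks, or distance-dependent motion
artifact. Passing tests therefore certify the *computational* properties of
the indices — formula correctness, invariances, recovery of planted
structure at realistic SNR — not their biological validity on scanner data.

## Problem sizes

The shipped analyses run at desk scale by choice: coupled pairs at up to
139,269 voxels (the reference in-mask count), BOLD phantoms of 20×20×12 ×
400 frames, oracle checks on 3×3×3 lattices, cohorts of ~10 subjects. All
generators accept larger dimensions.
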