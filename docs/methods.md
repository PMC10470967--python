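# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic data do and do not emulate, and the known
limitations of the study design.

## Frame, phantoms and intensity conventions

All images live on the square `[-1, 1]²` with `y` up; a raster of side `S`
samples pixel centers (no area anti-aliasing), so point-in-ellipse membership
is exact and additive densities sum exactly.  The head phantom is the
standard ten-ellipse table (densities 1.0, −0.8, −0.2, −0.2 and six of 0.1);
the test variant alters rotations and two semi-axes while keeping the skull
identical, so the test object is *out of training* but of the same family.
Raw summed densities may be negative; clipping is a display operation only
and never precedes projection.

The breast phantom is an attenuation map (dB/MHz^y·cm): water bath disk of
radius 0.95 (α₀ = 1.0), fat disk of radius 0.72 (1.2), a fibroadenoma
(r = 0.18 at (−0.25, 0.15), 0.7) and a cancer inclusion (r = 0.12 at
(0.28, −0.22), 1.0).  Tissue tables also carry density and sound speed for
completeness, but only attenuation is imaged: the acquisition model is
amplitude-based (below), not a full acoustic wave simulation — time-of-flight
and refraction physics are deliberately out of scope.

Reconstructed images in the comparison experiment are stored the way an
8-bit imaging pipeline stores them: densities on `[0, 1]` map affinely to
`[0, 255]`, negatives (FBP undershoot) clip to 0, values round to integers.
Metrics use `MaxValue = 255` on this scale.

## Tomography

A projection value is the exact line integral of the pixel-constant image:
per view, a Siddon-style sweep sorts each ray's crossings with all grid
lines and accumulates segment-length × pixel-value.  The same per-angle
sparse matrices serve as the SART system model, so algebraic fixed-point and
residual-decrease properties hold exactly rather than approximately.  For
*data synthesis* the projector models a finite detector: each radial sample
averages 4 sub-rays across the detector width (a single exact ray picks up
stair-step aliasing from pixelized edges which the ramp filter then
amplifies; 4-fold averaging suppresses it).  Radial samples are one pixel
wide, symmetric about 0, `ceil(√2·S)` rounded to odd so the frame corners
are covered.

FBP filters each row by `|ω|` sampled on a zero-padded FFT grid (≥ 2× the
row, power of two; optional Hann apodization) and back-projects with linear
interpolation, scaled `π / n_angles`.  SART uses the Andersen-Kak update

    f_j += λ · Σ_i [ a_ij (p_i − (A f)_i) / Σ_j a_ij ] / Σ_i a_ij,

sweeping angles sequentially; defaults λ = 1, 20 sweeps, zero start.  Rays
that miss the grid are skipped with a warning.  The residual norm is
non-increasing on consistent data (tested); on noisy data SART regularizes
by early stopping, and 20 sweeps was fixed a priori as the package default.

**Ring rebinning.** Transducer `k` of `N` sits at angle `2πk/N` on a circle
of radius `R = 0.95`.  An ordered pair `(i, j)` measures the chord whose
perpendicular direction is `ψ = π(i+j)/N`; the pair is assigned to view
`⌊((i+j) mod N)/2⌋` (two adjacent `ψ` values per view), column `p·N + i` for
sum parity `p` — `N/2` views × `2N` samples (128 × 512 for N = 256).  The
signed offset is `R cos(π(i−j)/N)`, negated when `ψ ≥ π`.  Within a view,
duplicate offsets (reciprocal pairs) are averaged and cubic interpolation
resamples onto `N/2` equispaced offsets in `[−R, R]`, giving the final
square sinogram (128 × 128).  Ray ordering inside a view is a convention;
only the resampled sinogram is consumed downstream.

**Ring acquisition synthesis.** Received amplitude for a pair is
`A₀ / max(len, h) · exp(−∫ α dl)` — cylindrical spreading times Beer-Lambert
attenuation — with the path integral computed by dense bilinear sampling
(deliberately a *different* integrator from Siddon so the two can
cross-validate in tests).  The log-ratio against a water-only reference
acquisition cancels spreading and yields line integrals of the attenuation
difference; reconstructions add the known water background back before
scoring.  Optional multiplicative Gaussian amplitude noise (default 1% in
the breast study) models measurement error.  This emulates the geometry and
information content of a ring scan, not its wave physics: no diffraction,
refraction or frequency-dependent attenuation, so conclusions about
*acoustic* artifacts do not transfer.

## Enhancement operators

- **Bilateral filter**: direct windowed form, window radius `⌈3σ_s⌉`,
  defaults σ_spatial = 3 px and σ_range = 10% of the intensity span;
  normalized weights keep the output inside the local range and commute
  exactly with adding a constant.
- **BPDHE**: the 256-level histogram is smoothed with a 3-bin Gaussian
  kernel, split at local minima between peaks, each partition equalized into
  an output sub-range proportional to its input span, and the mean
  brightness restored (iterated rescale-and-clip, exact to < 0.001 when no
  mass clips).
- **SVE**: with `ξ = max(Σ_ref)/max(Σ)` for a same-size uniform-histogram
  reference (deterministic inverse-CDF raster, no RNG), the output
  `U(ξΣ)Vᵀ` is exactly `ξ · image` — a global contrast normalization; the
  implementation computes `ξ` from the two spectral norms directly.
- **Guided filter**: standard box-filter form, defaults radius 8,
  ε = 10⁻⁴ × (guide span)² (the literature states ε on a [0, 1] scale;
  images here are on arbitrary float scales).

In the detail chain the signed detail image is mapped affinely to `[0, 255]`
for SVE and mapped back, since the uniform reference presumes that range;
clipping is disabled there (standalone `sve()` clips).

## Sparse model

Degradation `V` is a Gaussian blur (σ = 1 px default); `D` averages
`s × s` blocks, which places LR samples at half-integer HR positions — the
same grid convention as the bicubic upscaler, so degrade/upscale is free of
the half-pixel shift plain decimation would cause (verified by an exact
ramp-roundtrip test).  Features are the four high-pass responses
`[1,0,−1]`, `[1,0,−2,0,1]` and transposes; 9×9 stride-1 patches of the four
responses concatenate to 324-dim vectors, reduced by PCA to 99.9% variance
(~30–55 dims in practice).  Flat patches (feature variance < 10⁻⁸) are
excluded; if more than 30 000 usable patches remain, a seeded uniform
subsample caps the training set.

K-SVD initializes from a seeded random subset of the data, recodes with
batch OMP (sparsity 3) each sweep and updates every atom by a rank-1 SVD of
its restricted residual; unused atoms are replaced by the worst-represented
signal.  A safeguard keeps a signal's previous code when the greedy recode
is worse (the dictionary is unchanged at that point), making the logged
training error provably non-increasing.  Default 15 sweeps.  The inner
coding runs in float32 (the correlation sweeps are memory-bound; the
safeguard re-evaluates accepted codes in float64); the public `omp_batch`
default is float64.  The HR dictionary solve uses a Cholesky factorization
of `QQᵀ` with a `10⁻⁸·tr/m` ridge fallback on rank deficiency.

Reconstruction codes every stride-1 feature patch of the upscaled test
image, synthesizes `A_h q̃`, overlap-averages uniformly, adds the detail to
the upscaled image and clips to its 8-bit/[input] range.  With all-zero HR
dictionaries the output equals the upscaled input exactly (tested).

## The comparison experiment and its protocol

The published experiment is self-contradictory about the test protocol (the
test sample is described both as an FBP reconstruction of 255×255 and as a
blur + downsampled image, while detail crops index up to pixel 460).  The
package adopts the one reading under which all reported numbers are jointly
reachable, which is also the standard evaluation of this algorithm family:

1. *Training*: head phantom at 256² → 128-angle sinogram + 1% Gaussian
   noise (seeded) → SART (λ=1, 20 sweeps) → 8-bit `y_h`;
   `z_l` = blur + 2× downsample.
2. *Test*: modified phantom rasterized at 510² → 128-angle noiseless
   sinogram → FBP at 510² → 8-bit: this is the HR test reference; its
   blur + 2× downsampled 255² version is the LR test sample.
3. Methods (nearest, spline, raw-detail sparse coding, enhanced MeSR)
   upscale the 255² sample back to 510²; PSNR/MSE are computed against the
   FBP reference, entropy and average gradient on each output alone.
4. The two dictionary methods share the LR side (features, PCA, K-SVD
   dictionary and test codes); they differ only in the HR detail image the
   coupled dictionary was solved against — so their comparison isolates the
   detail-enhancement chain exactly.

Interpolation rows are deterministic; dictionary rows are averaged over ten
seeds in the acceptance script and study runner.

**Known deviations from published values** (measured under the defaults
above; see the acceptance script output): interpolation PSNRs come out
~2–4 dB *above* the published 23.88/25.35 dB — this projector/FBP chain
leaves less unrecoverable high-frequency noise in the reference than the
original pipeline apparently did — and the raw-detail baseline reaches
~32.8 dB (published 29.30).  The enhanced-detail variant scores *below* the
raw-detail baseline here (10-seed mean ~26.3 dB vs the published 31.06, with
~±1 dB seed variance), and its entropy/average-gradient (~5.8 / ~3.7) sit
above the published 4.49 / 2.76.  The mechanism is visible in the detail statistics:
with a training image as clean as 1% projection noise yields, the raw
detail is already a near-ideal regression target, while BPDHE's
partition-wise equalization remaps region levels into the enhanced detail,
which the guided filter's local linear model preserves rather than removes.
The chain's denoising premise pays only for substantially noisier training
reconstructions than this study's default produces.  These gaps are
reported as measured; no parameter was adjusted toward the published
numbers.

The breast study mirrors the pipeline on ring data (SART trains, FBP is the
test input, dictionary size 120).  In this synthetic stack FBP of the
rebinned data slightly *out-scores* SART against the phantom (SART's exact
ray model fits rebinning irregularities that FBP's interpolating
backprojection smooths), so the qualitative "iterative beats analytic"
expectation is not reproduced either; the pipeline asserts structure and
determinism, not that inequality.

## Problem sizes and determinism

Default sizes (256² training, 510² reference, 30 000 training patches,
1000 atoms, 15 K-SVD sweeps, 10 seeds) keep a full study around ten minutes
on one CPU; unit tests use 32–128² images and dictionaries of 32–200 atoms.
Every stochastic stage takes an explicit seed; runs are bit-identical given
the configuration (single-threaded BLAS), and the experiment runners can
write a manifest (config, versions, SHA-256 of outputs) for audit.

## Limitations

- The acquisition models are geometric/information-theoretic stand-ins, not
  physics simulations; quantitative transfer to measured ring-array data is
  untested.
- BPDHE on continuous-histogram reconstructions is sensitive to histogram
  partitioning; the detail chain inherits that sensitivity (seed variance of
  the enhanced method's PSNR is ~±1 dB at the default design point).
- Single scale factor (integer, default 2) and grayscale images only; no
  global back-projection consistency step after detail synthesis.
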