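# Methods

This document records the models implemented in `elite_mri`, the default
parameters and their units, and the numerical decisions that matter when
interpreting results.

## 1. Digital reference object (DRO)

`phantom.make_label_map` builds a six-region 2-D breast slice: background,
an elliptical breast with a skin rim, fibroglandular interior, an embedded
lesion (position jittered by the seed), a posterior pectoral-muscle band and a
small heart disc. Matrix sizes below 32 are rejected.

Each tissue has a baseline signal, a multiplicative enhancement amplitude and
a wash-in rise time drawn from a per-tissue dictionary
(`RISE_TIME_DICTIONARY`, seconds). The enhancement shape is the
peak-normalized 2CXM tissue curve (section 4); the drawn rise time rescales
(Fp, PS) jointly by `base_rise / rise_time` so that shorter rise times mean
proportionally faster wash-in. Pixel value at frame t is
`baseline * (1 + amplitude * e(t))`; a smooth multiplicative Gaussian field
(SD = `heterogeneity`, default 0.05) perturbs the amplitude per pixel so
region Casorati matrices are not exactly rank 1. Background stays exactly
zero. Coil sensitivities are smooth complex maps from Gaussian-weighted coil
centres placed around the FOV.

Realism limits: single 2-D slice, no respiratory or cardiac motion, no B0/B1
effects, magnitude-only ground truth, enhancement curves are spatially uniform
within a tissue up to the heterogeneity field.

## 2. Radial encoding operator E

`golden_angle_trajectory`: spoke i has angle `i * 111.246 deg (mod 180)`;
each spoke samples the k-space diameter uniformly through k = 0 with readout
length 2x the matrix (radii in [-0.5, 0.5) cycles/pixel). `bin_spokes`
assigns spokes to frames sequentially; trailing spokes that do not fill a
frame are discarded (frame index -1). Temporal resolution is
`scan_time * spokes_per_frame / n_spokes` seconds.

The NUFFT is hand-rolled Kaiser-Bessel gridding: width-4 kernel on a 2x
oversampled grid with the Beatty beta, a precomputed sparse interpolation
matrix, centred orthonormal FFTs and analytic sinh deapodization. The forward
and adjoint share the same sparse matrix, so `<y, Ex> = <E^H y, x>` holds to
machine precision (the acceptance suite checks ~1e-15, asserts 1e-5).

Density compensation starts from the analytic ramp (|k|, centre floored at
half a cell) and is refined internally with 50 Pipe-Menon iterations; a DC
calibration constant (`EncodingSpec._scale`) normalizes the operator gain, and
per-frame gains are applied in the plain gridding reconstruction so frame
intensity does not depend on the spoke count per frame. Both E and E^H work
in the sqrt(density)-weighted data domain, which makes the least-squares
objective the density-weighted one.

Numerical caveat: radial spokes never sample the k-space corners
(|k| > 0.5), so image content with energy there lies in the near-null space
of E. Solver-correctness checks therefore use band-limited test objects
(Gaussian-filtered noise); on broadband objects any reconstruction method is
under-determined in the corner directions.

## 3. Reconstruction

All iterative methods minimize

    1/2 ||y - E M||^2 + lambda ||S M||_1

with S the frame-to-frame temporal difference, by nonlinear conjugate
gradient (Fletcher-Reeves, Armijo backtracking with cached operator
products, smoothed l1 with epsilon tied to the image scale). `lambda`
(default 0.01) and the l1 smoothing (1e-6) are relative to the peak magnitude
of the initializer, the density-compensated adjoint E^H y, so they are
invariant to global data scaling. Defaults: 7 iterations x 3 restarts.

- `nufft_recon`: density-compensated adjoint (gridding), the non-iterative
  baseline.
- `grasp_recon`: the unconstrained problem over all frames (GRASP).
- `subspace_recon`: the same objective with M constrained to per-region
  temporal subspaces, `M_i = U_i V_i`, solving for the coefficients V with
  the bases fixed. The region partition selects the flavour:
  - whole image -> global low rank (GLR),
  - overlapping blocks (default 10x10 grid, 50% overlap, averaged on
    expansion) -> locally low rank (LLR),
  - tissue label map -> ELITE.

Bases come from `estimate_basis`: per-region SVD of the T x M Casorati matrix
of a low-resolution or preliminary reconstruction, without mean-centring
(the model has no intercept), keeping K = 6 components per tissue and
K_background = 1 for the background region; regions smaller than K reduce K
with a warning. Sign convention: each basis column is rotated so its
largest-magnitude entry is positive real. Rank-K truncation satisfies the
Eckart-Young identity (residual power = discarded Gram eigenvalues), which
the tests verify against an independent eigendecomposition oracle.

`kmeans_partition` offers a label map from clustering pixel time-courses when
no anatomical segmentation is available.

## 4. Pharmacokinetics (2CXM)

State equations (concentrations in mM, rates Fp and PS in 1/min converted
internally to 1/s, volume fractions dimensionless, ve + vp <= 1):

    vp dCp/dt = Fp (Ca - Cp) + PS (Ce - Cp)
    ve dCe/dt = PS (Cp - Ce)
    Ct = vp Cp + ve Ce

Two integrators agree to <0.1% of peak and are cross-checked against an
independent RK4 oracle in the tests:

- `method="conv"`: eigendecomposition of the 2x2 system and exact exponential
  convolution of the piecewise-linear AIF (fast; used inside fitting),
- `method="ode"`: adaptive LSODA.

Degenerate limits vp = 0 (instant plasma equilibration) and ve = 0 / PS = 0
(one-compartment) are handled in closed form. The derived transfer constant
is `Ktrans = Fp (1 - exp(-PS/Fp))` (1/min).

The AIF is a population-shaped bolus (`standard_aif`: gamma-variate peak,
default 6 mM, plus sigmoidal washout tail) with configurable onset;
`population_aif` averages measured AIFs after aligning each to its detected
onset (first sample above 10% of peak), and `shift_aif_onset` re-places the
averaged curve at a target onset time.

Signal <-> concentration uses the steady-state spoiled gradient echo
equation with defaults T10 = 1.3 s, TR = 4.87 ms, flip = 10 deg,
r1 = 4.5 /mM/s; M0 is estimated from a pre-contrast baseline window, and
samples implying negative concentration are clipped to zero with a warning.

`fit_pkm` is a bounded multi-start trust-region least-squares fit of
(ve, vp, Fp, PS); `bootstrap_fit` repeats the fit on random voxel subsets
(default 10% of the ROI without replacement, 100 replicates) and reports
per-parameter mean and SD.

Identifiability caveat: Fp is constrained by the first pass, so recovery
accuracy depends strongly on temporal resolution. At 1.4 s sampling (the
2-spoke frame rate) the median Fp error under 2%-of-peak noise is ~8%;
at 4.2 s (8-spoke frames) it roughly doubles. Ktrans is far more robust
(~1-2% in both regimes).

## 5. Residual CNN denoiser

A small numpy-implemented residual CNN (default 10 conv layers, 64 channels,
3x3 kernels, ReLU, global skip: `output = input + correction`) trained with
Adam on MSE to map 2-spoke gridding frames to fully sampled (Nyquist,
ceil(pi/2 * matrix) spokes) references of the same object. Training data come
from the DRO with rise-time augmentation (`augment_training_set`: each variant
redraws all tissue rise times from the dictionary; `n_cases * n_aug` phantoms).
Training is deterministic for a fixed spec seed. With all weights zero the
network is exactly the identity, and the backward pass is verified against
finite differences.

Inference (`ResidualDenoiser.apply`) processes frames in chunks of 4 without
layer caches (bounding memory) and by default averages the prediction over
the four axis-flip orientations, which removes orientation-dependent bias of
the learned correction.

Caveat: at 2 spokes/frame the aliasing is deterministic, so ROI-mean curves
of weak or thin tissues (muscle, skin, heart in the default DRO) are
artifact-dominated in the *input*; no frame-wise denoiser can restore
temporal fidelity there. Curve-fidelity checks in the tests therefore assert
high correlation only for tissues whose input curves carry signal
(input-vs-truth r > 0.8), and require at least two such tissues.

## 6. Metrics

- Noise SD: consecutive post-injection frame differences pooled over
  background rectangles, divided by sqrt(2) (the difference of two frames
  sharing the object doubles the noise variance). Rectangles (size scaling
  with the matrix, 8 px at 160) are placed greedily in pure-background rows.
- CNR: |mean lesion - mean fibroglandular| at the peak-lesion frame over the
  noise SD.
- Curve similarity: Pearson r on raw ROI-mean curves plus the l2 norm of the
  peak-normalized difference (shape error). Constant curves give r = NaN.
- `fold_change` tabulates CNR and inverse-noise fold changes vs a reference
  method.

Because the noise estimator is applied to magnitude images, it is accurate
when a signal pedestal dominates the noise or when noise is the residual of
an iterative reconstruction; on raw zero-mean background magnitude it is
biased low by rectification (this is inherent to magnitude DCE data, not a
bug).

## 7. Problem sizes and runtime

Defaults mirror a realistic breast protocol scaled to 2-D: 160x160 matrix,
8 coils, 288 spokes over 150 s, 8 spokes/frame (36 frames at 4.2 s).
The full benchmark (simulate + nufft + grasp + elite + metrics) runs in
~2 minutes on one CPU. Tests and oracles use 24-48 px matrices, where dense
operator matrices and Nyquist-sampled acquisitions are cheap.

## 8. File formats

HDF5 for phantoms (labels, kinetics, coils, time grid), k-space (complex64
samples, trajectory, frame assignment, density weights) and reconstruction
sidecars (config, objective trace, bases/coefficients); NIfTI (H, W, 1, T,
frame spacing in the 4th zoom, onset in toffset) for image series; CSV for
AIFs and bootstrap tables; JSON for metrics reports.
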