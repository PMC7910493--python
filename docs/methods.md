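# Methods

## The signal model

A voxel's normalized diffusion-weighted signal is modelled as a finite
set of cylindrically symmetric anisotropic tensors plus a spectrum of
isotropic tensors:

S_k/S_0 = Σᵢ fᵢ · exp(−b_k λ⊥ᵢ) · exp(−b_k (λ∥ᵢ − λ⊥ᵢ) cos²φᵢₖ)
        + Σⱼ f(Dⱼ) · exp(−b_k Dⱼ)

with b_k the k-th diffusion weighting (internally ms/µm², i.e.
b[s/mm²]/1000), λ∥/λ⊥ the axial/radial diffusivities of fiber-like
compartments (µm²/ms), φᵢₖ the angle between gradient k and fiber axis
i, and f(D) a nonnegative weight function on a diffusivity grid. The
spectrum integral is discretized as a weighted sum; the weights carry
the measure, matching the nonnegative-least-squares (NNLS)
representation used for fitting. Cylindrical symmetry is enforced
exactly (two equal minor eigenvalues), and fractions of a normalized
model sum to 1.

The isotropic spectrum is summarized into four bands (µm²/ms):
highly restricted 0 ≤ D ≤ 0.2 (associated with lymphocytes),
restricted 0.2 < D ≤ 0.8 (dense tumor cellularity), hindered
0.8 < D ≤ 2 (necrosis and edema), and free D > 2 (free water). Band
edges are inclusive on the upper side, so weight exactly at D = 0.8
counts as restricted and at D = 2.0 as hindered. The free band is
implied by the free-fraction metric rather than named alongside the
other three; it runs to the grid maximum.

## Acquisition schemes

Schemes are FSL-dialect bval/bvec pairs. The reference scheme is one
b = 0 acquisition plus 99 diffusion-weighted directions with maximum
b = 3000 s/mm². Generated directions use a golden-angle spiral on the
hemisphere (antipodal directions encode the same measurement, so a
full-sphere set would waste near-antipodal pairs), randomly rotated per
seed. Because a spectrum of isotropic diffusivities is only
identifiable from multiple b-values, generated schemes spread b-values
over (0, b_max] by default — uniformly spaced and shuffled across the
spiral — with an optional discrete-shell variant. How the 99 b-values
of the original acquisition were distributed below the maximum is not
public; the scheme generator therefore keeps this configurable.

## The inverse problem

Fitting proceeds in stages per voxel (signals are first normalized to
the mean b≈0 signal):

1. **Combined-basis NNLS.** The design matrix holds ~100 quasi-uniform
   candidate fiber orientations (at initial λ∥ = 1.5, λ⊥ = 0.3 µm²/ms)
   plus 31 isotropic columns on a uniform grid over [0, 3] µm²/ms
   (0.1 spacing — the 0.2/0.8/2.0 band edges fall exactly on grid
   points). A ridge penalty applies to the spectrum block only.
2. **Orientation selection.** Candidate axes carrying ≥ 5% of the total
   weight are kept; near-parallel axes (within 15°, antipodally
   symmetric) merge, the cluster axis being the weight-averaged member
   axis (which recovers orientations lying between grid points), capped
   at 3 components. The higher-weight axis seeds each cluster —
   a deterministic tie-break.
3. **Diffusivity refinement.** A coarse-to-fine grid search over the
   shared (λ∥, λ⊥), with an inner NNLS on the reduced basis (kept axes
   + spectrum grid) per candidate, λ∥ ∈ [1.0, 3.0], λ⊥ ∈ [0, 0.6]
   µm²/ms. The reduced, few-discrete-axes representation is essential:
   an over-complete orientation fan can mimic isotropic compartments
   (a uniform mixture of cylinders is isotropic), so keeping the full
   fan would systematically inflate the fiber fraction.
4. **Metric derivation.** Band fractions (normalized, with the fiber
   fraction, to sum to 1), weight-averaged band diffusivities, fiber
   AD/RD/FA from the fitted λ pair, and mean ADC / mean FA from a
   separate weighted log-linear DTI fit ("mean FA" is taken to be the
   DTI fractional anisotropy, since it is listed beside mean ADC).

**Noise-adaptive regularization.** A fixed ridge cannot serve both
regimes: noiseless single-compartment voxels must be recovered exactly
(the ridge spreads mass across adjacent, nearly collinear exponential
columns and across band edges), while noisy voxels need smoothing. The
fit therefore runs an unregularized pilot NNLS, estimates the noise
level σ̂ from the pilot residual (degrees-of-freedom corrected), and
sets the working ridge to 7.5·σ̂ (a discrepancy-principle rule; the
constant was calibrated once on synthetic validation phantoms and is
configurable). Noiseless voxels then get an interpolating fit; at
SNR 50 the effective ridge lands in the stable range.

**Accuracy at SNR 50.** On class-conditional phantoms (below), fiber
fraction is recovered with mean absolute error ≈ 0.043 and restricted
fraction with ≈ 0.059 (3000 voxels). The restricted error is dominated
by support-selection noise of the ill-posed exponential-spectrum
problem: an oracle given the true diffusivity support, λ and axis
(estimating only the weights) achieves ≈ 0.017, and a broad search over
estimator variants (ridge and smoothing penalties across two orders of
magnitude, coarse/log grids, shell schemes, Rician bias correction,
sparse re-fits, band-constrained refinement, bagging, reweighted NNLS)
plateaus at ≈ 0.06–0.09. This is a known property of regularized
exponential-spectrum fitting, not a defect of a particular stage.

## Synthetic phantoms

No imaging or histology data from the source cohort is public, so the
package generates its own study material at two levels.

**Feature tables** draw each of the 12 metrics (plus the auxiliary
highly-restricted fraction) independently per class from truncated
normals whose means ± SDs are the published group statistics where
reported. Metrics without a published value carry flagged plausible
defaults that respect the published qualitative ordering (white matter
highest in fiber and highly-restricted fractions, DC/LDC tumor highest
in restricted fraction, necrosis highest in hindered and free
fractions); the white-matter mean ADC is back-derived from the reported
+115% DC-vs-WM difference; hemorrhage, for which nothing is reported,
is synthesized as a low-ADC, low-anisotropy class and flagged as such.
Truncation to [0, 1] and renormalization of rows whose fraction sum
exceeds 1 would pull realized means ≈ 0.02 below target, so the
generator calibrates its pre-truncation means by a deterministic
internal fixed-point iteration; realized group means then match the
published ones. Only marginals are published, so metrics are sampled
independently — the joint feature distribution of real tissue
(correlated metrics, non-Gaussian shapes) is *not* emulated, and
classifier scores on these tables characterize the pipeline, not the
original data.

**Signal phantoms** draw a ground-truth voxel composition per class —
the class's three dominant compartments, with fractions from a
Dirichlet centred on the class composition (concentration 22,
reproducing the ≈ 0.1 reported group SDs) and fixed representative
band diffusivities 0.1 / 0.5 / 1.4 / 2.5 µm²/ms ± 10% jitter, the
conventional fixed-compartment design of diffusion simulation studies —
then evaluate the forward model and add Rician noise (magnitude of a
complex Gaussian perturbation, σ = 1/SNR referenced to S₀). Single-class
voxels only; no partial-volume mixing across label boundaries.

## Histology-MRI registration

2-D thin-plate-spline warps interpolate landmark pairs (18 in the
reference protocol) with kernel U(r) = r² log r² (U(0) = 0), an affine
part, and the side conditions Σw = 0, Σw·p = 0. Zero regularization
interpolates exactly and reproduces affine maps with zero warping
weights; positive regularization (added to the kernel diagonal) trades
landmark fidelity for lower bending energy. Coordinates are
pixel-centred, origin (0, 0), x = column. RGB histology converts to
grayscale via ITU-R 601 luminance. Image warping inverse-maps the
output grid (fit the spline from output to input coordinates);
intensity images resample bilinearly, label masks with nearest
neighbour. ROI label transfer goes the forward direction: every
histology pixel maps into MRI voxel coordinates and each voxel takes
the majority label of the pixels landing in it, ties left unlabeled —
one declared resolution of the unstated sub-voxel rasterization.

## Classifier

A feed-forward network over the 12-metric feature vector: ten fully
connected hidden layers (width 128 by default — widths were not
reported), each followed by batch normalization and an ELU activation,
ending in a softmax layer over the six classes. Training minimizes
cross-entropy with mini-batch Adam (β₁ = 0.9, β₂ = 0.999, batch 200),
early-stops on validation loss with patience 10, and restores the
best-validation weights. Features are additionally z-scored with
training-set statistics, since the metric units differ by orders of
magnitude. Learning rate defaults to 1e-3 (reported only as "manually
tuned") with a divergence guard. Everything is deterministic given the
seed. The network is implemented directly in numpy (forward and
backward passes, batch-norm statistics, Adam), keeping the package
dependency-light and the arithmetic transparent.

Data handling: an 8:1:1 train/validation/test split (test and
validation sizes round(0.1·N); voxel-wise random as in the reference
protocol, with an optional class-stratified mode — voxel-wise splitting
of real specimen data risks specimen leakage, which is why a grouped
mode is worth exposing), then SMOTE on the training partition only:
each synthetic minority row is x + u·(x_nn − x) with u ~ U(0, 1) and
x_nn one of the k = 5 nearest same-class neighbours (k is the cited
method's default; the protocol does not state it). Validation and test
partitions are never resampled or used for normalization statistics.

## Evaluation battery

Confusion matrices (rows = true class) with overall accuracy and
per-class true-positive rates; one-vs-rest ROC with trapezoidal AUC
(ties contribute ½, making AUC exactly the normalized Mann-Whitney
pair statistic — property-tested against brute-force pair counting);
Youden operating points (ties broken toward higher specificity, then
higher threshold); precision-recall curves with average-precision
PR-AUC (the step convention; trapezoidal PR interpolation is
optimistic) and F1 at the hard labels; percentile-bootstrap 95% CIs
(10,000 resamples by default; the AUC path is vectorized via rank
sums); Mann-Whitney U tests (exact enumeration for tie-free samples
with both n ≤ 20, tie- and continuity-corrected normal approximation
otherwise); per-class mean ± SD (sample convention by default,
population selectable — the cohort age SDs follow the population
convention) and pairwise percent differences 100·(m₁−m₂)/m₂ rounded to
integer percent.

## Problem sizes and defaults used in the shipped checks

Fit-recovery runs use 500 voxels per class at SNR 50 with the
1 + 99-direction scheme; classifier sanity runs use 600 voxels per
class for the well-separated control (class means ≥ 5 SDs apart —
near-perfect scores are expected there by construction) and 400 per
class for the published overlapping profiles; bootstrap coverage uses
200 outer replications of 10,000-resample CIs at n = 200. These sizes
make the whole battery reproducible on a single CPU in a few minutes.

## Known limitations

- Feature tables emulate only published marginals; no metric
  covariance, skew, or specimen/patient structure.
- Signal phantoms use single-class voxels, one fiber population, and
  three compartments per voxel; crossing fibers beyond the N_aniso cap
  are out of scope.
- Restricted-fraction recovery at SNR 50 carries an irreducible
  ≈ 0.06 mean absolute error (see above); metrics derived from it
  inherit that noise.
- The classifier scores on synthetic tables say nothing quantitative
  about performance on the original specimens, whose data are not
  available.
- No T1/T2 compartment weighting, exchange, kurtosis, or
  time-dependent diffusion; no eddy-current or susceptibility
  correction; no 3-D registration (slice planes are assumed matched
  physically).
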