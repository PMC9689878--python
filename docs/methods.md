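# Methods

This note records the models implemented in `spectrace`, the
assumptions behind them, the choices made where the standard protocol
leaves room, and what the synthetic benchmark does and does not
demonstrate.

## Data model

A spectrum is absorbance (AU) on a strictly descending, uniformly
spaced wavenumber grid; the default instrument geometry is
10,000–4000 cm⁻¹ at 1557 points (≈ 3.856 cm⁻¹ spacing). Binned axes
produced by block averaging (e.g. 1557 → 64 bins of 24 or 25 points)
are only near-uniform; the grid container therefore takes an explicit
spacing tolerance, strict (1e-9 relative) for instrument grids and
≈ 1/bin-size for binned ones.

## Synthetic generator

The generator emulates a multi-origin herbal FT-NIR collection and is
the benchmark for every downstream stage. Its components, with
defaults:

* **Bands.** Seven Gaussian peaks at 4280, 4400, 4750, 5170, 5800,
  6800, 8300 cm⁻¹ (widths 60–180 cm⁻¹, amplitudes 0.25–0.90 AU) on a
  gentle scattering baseline — the C–H/O–H/C–O overtone and
  combination bands of a polysaccharide-rich plant powder.
* **Class effects.** Five of the seven bands (4400, 4750, 5170, 6800,
  8300 cm⁻¹) carry per-class amplitude multipliers 1 ± U(0.12, 0.30)
  with random sign; each class additionally has one minor marker band
  (0.06 AU, width 45 cm⁻¹) at a class-unique position in the
  6050–7750 cm⁻¹ region. The ground-truth "informative indices" are
  the ±0.4 σ core windows of the five class-effect bands, where the
  band holds ≥ 92 % of its peak amplitude and between-class variance
  is strongest; the weak marker windows are recorded separately and
  excluded from the guaranteed-recovery contract.
* **Within-class compositional gradient.** Each sample sits at
  1 + s, s ~ N(0, 0.5), along its class's band-effect signature (the
  deviation of the class mean from the class-neutral base, plus half
  of the marker band). This emulates the compositional spread of a
  field collection — samples from one region share a direction of
  variation — and is what gives the per-sample dynamic spectra of
  2DCOS their class-specific covariance structure. Without it,
  within-class variation is pure scatter and noise, and per-sample
  correlation maps carry essentially no class information.
* **Scatter and noise.** Per sample, x → a + b·x with
  b ~ LogNormal(0, 0.1), a ~ N(0, 0.02 AU), plus additive
  N(0, 0.003 AU) noise — the distortion family MSC is built to remove.
* **Outliers.** Five rows (of 207; class sizes 14, 20, 32, 32, 9, 12,
  14, 21, 40, 13 mirror a 15-site collection) receive a gross affine
  corruption x → (1 + m)x + m, m = 0.5.
* One `numpy` Generator seeded from the config drives everything;
  identical configs are bit-identical.

What the generator does **not** emulate: instrument line shapes,
water-vapor interference, wavelength-axis drift, class-specific
covariance beyond the single compositional direction, and non-affine
scatter. Passing tests therefore demonstrate algorithmic correctness
and qualitative behaviour under controlled conditions, not performance
on real spectra.

## Preprocessing

MSC regresses each row on the mean spectrum (or a supplied reference)
by closed-form simple OLS and returns (x − a)/b; a zero-variance
reference is rejected. SD is the Savitzky–Golay second derivative with
window 15, polynomial order 2 — common NIR practice — using the grid's
physical spacing so units are AU/(cm⁻¹)² (values ~1e-5; downstream
degeneracy checks are therefore relative, never absolute). Edges are
evaluated from the boundary polynomial fits, keeping output length
equal to input so grids stay aligned for 2DCOS. The combined chain is
MSC **then** SD: scatter correction before differentiation.

## Outlier gating

Mean-centered SVD; Hotelling's T² over the first A = 2 score
dimensions (the score-plot convention), limit
A(n−1)/(n−A)·F₀.₉₅(A, n−A). Gating runs once on the raw spectra
before any split, with global (not per-class) statistics. Centering
only — no variance scaling — as usual for absorbance spectra.

## Kennard–Stone splitting

Classic maximin: seed with the most distant pair, then repeatedly add
the sample maximizing its minimum distance to the selected set; ties
break to the lowest row index, making splits bit-reproducible. Set
sizes are round-half-up on n·fraction with the final set taking the
remainder — 202 samples at 70 % give 141/61, and 60/30/10 gives
121/61/20. (A three-way 60/30/10 split of 202 samples cannot yield the
counts 122/51/19, which sum to 192; the fractions, not those counts,
are authoritative here.) For three-way splits KS selects train from
all samples, then test from the remainder; the leftover is the
validation set.

## PLS-DA

NIPALS PLS2 on mean-centered X and centered one-hot Y (no
unit-variance scaling — spectral convention), inner iteration to
|Δu| < 1e-12 or 500 iterations, X and Y deflation per component.
Prediction uses the accumulated coefficients B = W(PᵀW)⁻¹Cᵀ; class =
argmax, ties to the lowest class index. Cross-validation uses
class-stratified round-robin folds after a seeded shuffle (k = 7);
Q² = 1 − PRESS/SSY pooled over folds, RMSECV = √(PRESS/(nK)). The
latent-variable count is the first global maximum of Q²(A) (a
first-local-maximum rule is available as a toggle). VIP uses
SSYₐ = ‖tₐ‖²‖cₐ‖²; the identity mean(VIP²) = 1 is asserted in tests.
The permutation test refits at fixed A for uniformly permuted labels,
regresses R² and Q² on the fraction of labels left in place (the
unpermuted model enters at abscissa 1), and reports the intercepts;
the conventional no-overfit call is R²-intercept < 0.4 and
Q²-intercept < 0.

## Wavelength selection

* **VIP**: strictly greater than 1; an empty selection is an explicit
  error because downstream models need at least one variable.
* **SPA**: chains of minimally collinear variables by repeated
  orthogonal projection (deflation of the residual matrix), all start
  variables by default; every chain prefix is scored by validation
  RMSE of a PLS-DA model on an internal 70/30 Kennard–Stone split,
  with the component count fixed once by inner CV (capped by subset
  size). Minimum RMSE wins; ties prefer the smaller subset, then the
  earlier start.
* **CARS**: 50 Monte-Carlo runs at 80 % calibration sampling;
  variable weights are normalized |PLS-DA coefficients| summed over
  classes; the retained count follows the exponentially decreasing
  schedule r₁ = 1, r_N = 2/p (ceiling), enforced by a weighted draw
  without replacement; the component count is fixed once by 7-fold CV
  before the runs. The run with minimal 7-fold RMSECV provides the
  selection. A pool collapse below 2 variables truncates the runs
  with a warning.

## SVM

RBF-kernel SVC (libSVM SMO, one-vs-one multiclass) with an exhaustive
grid search over c ∈ 2⁻⁵…2²⁰ and g ∈ 2⁻¹⁵…2³ (step 1 by default,
configurable to 0.5 or coarser), scored by 7-fold CV accuracy with the
same stratified folds as PLS-DA; ties break to the smallest c, then g.
Features are used unscaled (spectra share units); note that with
multiplicative scatter present, Euclidean/RBF distances are dominated
by the scatter slope, so the RBF SVM on raw scatter-affected spectra
is structurally handicapped — scatter correction (or selection) first
is the practice the pipeline reflects. A zero-variable input raises an
explicit cannot-build error that the pipeline records as a failed
cell rather than a fatal stop.

## 2D correlation spectroscopy

Dynamic spectra of a class are deviations from that class's mean
(perturbation = sample index); the synchronous map is Φ = SᵀS/(m−1),
symmetric PSD by construction. Per-sample maps are the rank-1 outer
products d dᵀ/(m−1) of each sample's deviation, so the per-sample maps
of a class sum exactly to the class map; this is the one-image-per-
sample reading needed when each sample must yield a classifier input
(a per-class-map mode exists as well). Spectra are MSC-corrected
before the correlation transform in the pipeline — multiplicative
scatter otherwise dominates the deviations and buries the
compositional cross-peak structure the maps are meant to expose — and
block-averaged to 64 bins before correlating (identical pixel
semantics at a fraction of the memory of correlating 1557² first).
Maps render as 64×64 8-bit RGB PNGs through a fixed perceptually
uniform colormap with per-image min–max normalization.

Because a sample's own class mean defines its deviation, constructing
a test sample's map requires its label: the per-sample 2DCOS input is
intrinsically label-informed. This mirrors the upstream protocol (all
maps generated before splitting) and is the main reason the CNN on
2DCOS inputs approaches ceiling accuracy; the leak-free mode confines
the class means themselves to training rows, but the label dependence
of the construction remains and is flagged here deliberately.

## Residual CNN

No deep-learning framework is used: the network is a self-contained
NumPy implementation with hand-written backpropagation, verified
against finite differences in the test suite. Architecture: one 3×3
stem convolution (stride 2, 8 channels), seven residual blocks of two
3×3 convolutions each (8→16→32 channels, stride-2 downsampling at the
width changes, identity skips with parameter-free subsample +
zero-channel-padding), global average pooling, and a linear
classifier — exactly 16 weight layers. Batch normalization follows
every convolution. Training: SGD with momentum 0.9, learning rate
0.01, weight decay 0.001 (convolution and classifier weights only),
batch 16, softmax cross-entropy, early stop after training accuracy
holds at 1.0 for two consecutive epochs. Everything runs in float32;
under a fixed seed and single-threaded BLAS, runs are bit-identical.
Spectrum-plot inputs are rasterized at 64×64 (block-averaged
wavenumber axis, dataset-wide intensity scale, filled vertical spans);
2DCOS inputs are the per-sample maps min–max normalized per image.

## Pipeline and leak control

One run executes {raw, MSC+SD} × {none, VIP, LVs, SPA, CARS} ×
{PLS-DA, SVM} on a shared 70/30 Kennard–Stone split, plus
{raw plots, MSC+SD plots, 2DCOS maps} × CNN on a 60/30/10 split, and
collects metrics, selections, overlaps, confusion matrices and
per-stage sample-index usage in a JSON-serializable report. In the
default leak-free mode the MSC reference is the training-row mean,
selections and latent-variable choices see training rows only, and the
report's leak audit can assert that no held-out index of a branch
entered any of that branch's fitted stages; a faithful mode that
preprocesses before splitting is available behind a flag. In the
"LVs" SVM cells the features are the PLS score projections, which is
why those cells have very few input dimensions. Cell failures (e.g.
an unbuildable SVM on an empty selection) are recorded per cell, not
fatal.

## Problem sizes and numerical choices

The test suite exercises oracle equivalences on ≤ 20×10 instances,
recovery simulations at the module-stated sizes (planted-variable
designs of 40–60 samples × 15–50 variables over 20 seeds; full-scale
207 × 1557 for VIP recovery and PLS-DA accuracy over 20 seeds; the
scatter-free separable configuration for the SVM accuracy check over
10 seeds), and CNN learnability at the full 64×64 × ~200-image scale
over 10 seeds (2DCOS) / 5 seeds (input ranking). The acceptance
script runs the full stage matrix with the SVM grid at step 3 and SPA
seeded from every 6th wavenumber — resolution choices that keep a
single-CPU run in minutes while leaving every algorithm's structure
intact. Degenerate-input policy throughout: refuse empty results
explicitly (empty selection, all-flagged outlier gate, empty split
sets) rather than propagate empty arrays; break all ties
deterministically (lowest index / smallest subset / smallest c then
g).

## Known limitations

* The synthetic benchmark is favorable to MSC by construction (its
  scatter is exactly affine); real scatter is only approximately so.
* Per-sample 2DCOS maps are label-informed (above); accuracies on
  that input overstate what a deployment without labels could achieve.
* SPA over all 1557 start variables with PLS evaluation is O(p²·A);
  the default budgets (start stride, max chain length) trade
  exhaustiveness for runtime and are configurable.
* The CNN targets ~200 images at 64×64 on CPU; it is not a
  general-purpose training stack.
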