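# Methods

## Problem setting

Circular cone-beam CT measures, at each of `Na` rotation angles, a 2-D
cone-beam projection of an object on an `N x N` flat detector.  Discretized,
the scan is a linear system `W x = y` with `x` the `N^3` attenuation volume
and `W` the cone-beam transform.  The FDK algorithm inverts this
approximately in three steps,

    FDK(y, h) = B_w( h *_1D r(y) ),

where `r` multiplies each detector sample by the ray cosine
`D / sqrt(D^2 + u^2 + v^2)` (`D` the source-to-detector distance, `(u, v)`
physical coordinates from the detector centre), `h *_1D` convolves every
detector row with a one-dimensional filter of length `2N`, and `B_w` is the
voxel-driven backprojection carrying the Feldkamp distance weight
`(D_so / (D_so + s))^2` (`D_so` source-to-axis distance, `s` the voxel
coordinate along the source-detector axis).

## The NN-FDK model

FDK is bilinear in `(y, h)`.  Parametrizing the filter by `Ne`
exponentially binned coefficients, `h = E h_e`, the value of voxel `v` in
`FDK(y, E h_e)` is the inner product of `h_e` with row `v` of the
`N^3 x Ne` matrix whose columns are FDK reconstructions with binned unit
filters ("feature volumes").  A two-layer perceptron with `Nh` hidden
nodes acting on that row,

    N_theta(q) = sigma( sum_k  xi_k * sigma(q . h_e^k - b_k) - b_o ),

is therefore exactly equivalent to running `Nh` FDK reconstructions with
the learned filters `E h_e^k` and combining them voxelwise through
sigmoids.  Training the voxelwise network on sampled voxels and deploying
it as `Nh` FDK runs is the whole trick: the model has
`(Ne + 2) * Nh + 1` trainable parameters (61 for `Nh = 4`, `N = 1024`),
orders of magnitude fewer than post-processing CNNs, and reconstruction
costs `Nh` FDK evaluations.

### Exponential binning

Filter taps are grouped radially around the centre tap with widths
1, 1, 1, 1, 2, 4, 8, ... (doubling after four unit bins), truncated at
radius `N`; the two mirror bins at equal radius share one coefficient
because FBP-type filters are symmetric.  This yields `Ne = 13` at
`N = 1024` and hence the 61-parameter count above, which is the
calibration the scheme was chosen to satisfy; the exact bin layout is
exported as JSON for reproducibility and is configurable in principle via
`BinningOperator`.  Expansion uses plain 0/1 indicator columns; the
conditioning cost of unnormalized columns is absorbed by the input
scaling below.

### Scaling conventions

The output node is sigmoidal, so grey values must live in (0, 1):
high-quality target voxels are mapped affinely from their ROI value range
into [0.05, 0.95] before training and the inverse map is stored with the
parameters and applied after reconstruction.  Each of the `Ne` feature
channels is z-scored over the training set (Levenberg-Marquardt
conditioning); at reconstruction time the affine map is fused into the
filters and biases (`h' = h / sd`, `b' = b + mu . h'`) so the volume route
and the voxel route agree exactly — this equivalence is tested to 1e-5
at `N = 16` and `N = 32` and is the central correctness property of the
implementation.

## Projectors

No GPU projection toolbox is assumed; the package ships three native
numba-compiled operators:

* forward: ray-driven marching with trilinear volume sampling, fixed step
  of half a voxel, midpoint rule between the ray's cube entry and exit
  points;
* backprojection: voxel-driven with bilinear detector interpolation;
* a pixel-splatting forward that is the exact transpose of the
  backprojector.

The ray-driven/voxel-driven pair is only approximately adjoint (measured
~1e-3 normalized on an 8^3 grid), as is typical; the adjoint test and the
SIRT+ iteration therefore use the matched splat/voxel-driven pair, whose
adjoint error is at floating-point level.  A backend registry allows an
external (e.g. GPU) projector to be plugged in; all tests run the native
one.

Numerical notes: at exactly axis-aligned angles the fixed-step quadrature
aligns with the voxel lattice and the integration error is a few times
larger than at generic angles (still ~3e-3 relative); the
trajectory-symmetry test runs on an offset angle grid for this reason.
Volumes are stored in 1/cm, geometry in mm, and path lengths are converted
so line integrals are the dimensionless Beer-Lambert exponent.

### FDK normalization

Standard filters are built in the spatial domain at the *virtual* detector
pitch (physical pitch / magnification, in cm): the band-limited ramp
(Ram-Lak) from its closed form (centre tap `1/(4 du^2)`, odd taps
`-1/(pi n du)^-2`), the Hann variant by apodizing the ramp's frequency
response with a Hann window vanishing at Nyquist.  The angular step
`2 pi / Na`, the half from full-circle redundancy, and the virtual pitch
are folded into the weighted backprojection, not the filter, so learned
filter coefficients remain comparable across `Na`.  With these
conventions noiseless Hann-FDK of a centred ellipsoid recovers the true
attenuation to within ~3% at `N = 64` (tested at a 10% tolerance).

## Training

Training pairs couple a voxel's feature vector to the same voxel of a
high-quality (HQ) reference reconstruction.  The ROI is the HQ object
support (global Otsu threshold) dilated by a Euclidean ball of radius
`round(0.2 N)` voxels; pairs are drawn uniformly without replacement,
disjoint between training and validation, with an equal count per source
dataset.

The half-SSE loss is minimized by Levenberg-Marquardt with the analytic
Jacobian (verified against central differences to 1e-5).  Defaults:
`lambda0 = 1e-2`, x10 on rejection, x0.1 on acceptance, at most 500
epochs, early stopping after 100 epochs without validation improvement;
one "epoch" is one full-batch LMA step, which is cheap because
`|theta| < 100`.  Damping is `lambda * I` by default with a
Jacobian-diagonal (`diag(J^T J)`) variant behind a config switch.  A step
is accepted only if it reduces the training loss; the returned parameters
are the earliest accepted iterate with the lowest validation loss, so the
result is never worse on validation than the initial guess.  Singular
normal equations escalate the damping rather than failing.

On a planted-network problem (`Nh = 2`, `Ne = 5`, 10^4 noiseless pairs)
this recovers the predictions to MSE below 1e-6 (observed ~1e-30).

## Simulation

Phantoms live on the unit cube, scaled to a 10 cm physical cube with a
relative intensity of 1 mapping to 0.22 1/cm (plastics at ~40 keV).  The
Fourshape family draws three of each of ellipsoid, cuboid, Gaussian blob
and 8-spoke Siemens star with sizes uniform in [0.05, 0.3] of the cube
width, intensities in [0.5, 1.5], uniform random orientations and centres
constrained (via per-axis bounding extents) to keep every primitive
inside the cube.  The Random Defrise family stacks non-overlapping flat
disks (radius [0.2, 0.3], half-thickness [0.01, 0.02], tilt up to 3
degrees) along the rotation axis; the standard variant has seven
equispaced equal-intensity disks symmetric about the midplane.
Voxelization supersamples 2x per axis for partial-volume handling.

Noise follows Beer-Lambert counting statistics: detected counts are
Poisson with mean `I0 * exp(-ybar)` and the measured line integral is
`-ln(max(counts, 1) / I0)`; the one-count clamp keeps fully absorbed rays
finite.  The HQ training target reconstructs a dense, low-noise scan
(`Na = 1500`, `I0 = 2^20`, 0.6 degree cone angle) with Hann-filtered FDK.

What the generator does **not** emulate: scatter, beam hardening,
polychromatic spectra, detector blur or afterglow, mechanical jitter.
Passing the simulated-data tests therefore demonstrates correctness of
the algorithmic chain and the expected noise/undersampling behaviour, not
robustness to the systematic physics of a real scanner.

## Evaluation

* TSE: `||mask (x_HQ - x_r)||^2 / (2 N_ROI)` — the training loss per ROI
  voxel; the identity between the two code paths is tested.
* SSIM: uniform 19-pixel window, scikit-image constants, computed per
  z-slice and averaged; ROI-masked by default (over the ROI bounding box)
  with the unmasked per-slice mean as the alternative.  Cross-checked
  against an independent direct-formula implementation to 1e-6.
* Segmentation masks are compared by signed volume error, mislabeled
  fraction, and Dice coefficient.  The volume error is kept signed; take
  its absolute value when tabulating.

## Baseline

SIRT+ iterates `x <- max(0, x + C W^T R (y - W x))` with `R`, `C` the
inverse row/column sums of the matched operator pair, starting from zero;
typical iteration counts are 200 (few-angle/high-dose) and 20 (low-dose).
Without the nonnegativity projection the iterate's row-weighted residual
approaches the weighted least-squares floor (tested against a direct
solve on a small explicit system).

## Desk-scale study sizes

The full-scale study conditions (`N = 1024`, `NT = NV = 10^6`) are kept
as defaults where they are cheap (parameter counting, CLI defaults with
automatic clipping to the ROI size).  The bundled end-to-end experiment
runs the high-noise comparison at `N = 64`, `Na = 32`, `I0 = 256` with 10
training datasets and `NT = NV = 3 * 10^4` pairs — the package's chosen
desk-scale problem — training one NN-FDK4 network and evaluating it
against Hann-FDK on 10 fresh Fourshape phantoms by TSE against the
ground-truth voxelization.  Under these conditions NN-FDK wins on at
least 9 of 10 test phantoms (typically 10/10, with roughly a 2x mean TSE
advantage at this noise level).

## Known limitations

* The native projectors are CPU-bound; `N = 1024` volumes are out of
  desk-scale reach (the backend registry is the extension point).
* Absolute FDK grey values depend on the stated normalization
  convention; a global scale difference against other implementations is
  expected and is absorbed by NN-FDK's learned scaling.
* Detector coverage requires `magnification * voxel_size <= pixel_size`;
  corner-cutting truncation for objects filling the full cube diagonal is
  possible at generic angles, as with any just-covering detector.
* LMA is a local optimizer: on hard planted problems a poor initialization
  can stall; the training seed is part of the experiment configuration.
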