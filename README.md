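# nnfdk — learned-filter FDK reconstruction for circular cone-beam CT

`nnfdk` implements the **NN-FDK algorithm**: the Feldkamp–Davis–Kress
(FDK) direct reconstruction for circular cone-beam CT, augmented with a
shallow two-layer perceptron whose first-layer weights are learned,
exponentially binned 1-D reconstruction filters.  It is aimed at
high-throughput CT settings (industrial inspection, lab micro-CT,
biological specimen imaging) where FDK is used for speed but its quality
degrades on noisy, few-angle, or large-cone-angle data, and where little
training data is available.

## The model

The scan is `W x = y` with `W` the cone-beam transform, and FDK is

    FDK(y, h) = Wᵀ_w ( h ∗ r(y) )₁D

(reweighting `r`, row-wise 1-D filtering with `h ∈ R^{2N}`, weighted
backprojection).  A filter is parametrized by `Ne ≈ log₂ N` exponentially
binned coefficients, `h = E h_e`.  Because FDK is bilinear in `(y, h)`,
the two-layer network with `Nh` hidden nodes

    N_θ(q) = σ( Σ_k ξ_k σ( q·h_e^k − b_k ) − b_o ),    θ = (ξ, b_o, h_e^k, b_k)

applied voxelwise to the rows of the feature matrix `F_y E` (the `Ne` FDK
reconstructions with binned unit filters) is *identical* to running `Nh`
FDK reconstructions with the learned filters and combining them through
sigmoids:

    N_θ( (F_y E)_{v:} ) = ( NN-FDK_θ(y) )_v .

The network has `(Ne+2)·Nh + 1` trainable parameters — **61** for
`Nh = 4`, `N = 1024` — and is trained in seconds by Levenberg–Marquardt
on voxel pairs drawn from a high-quality reference reconstruction.
Reconstruction costs `Nh` FDK runs.

The package provides the native CPU cone-beam projectors (ray-driven
forward, voxel-driven weighted backprojection, plus an exactly matched
adjoint pair for iterative methods), the FDK filters (Ram-Lak, Hann), the
exponential filter binning, the NN-FDK network and trainer, Fourshape and
Random Defrise phantom families with Beer–Lambert Poisson noise, a SIRT⁺
baseline, and TSE / SSIM / segmentation-overlap metrics.  See
`docs/methods.md` for conventions and assumptions.

## Worked example

Simulate a noisy 32-angle scan of a random Fourshape phantom at
`N = 64` (photon count `I0 = 256`), together with the high-quality
training target (1500 angles, `I0 = 2²⁰`, Hann FDK); train an NN-FDK₄
network; reconstruct; compare with Hann-filtered FDK:

```sh
$ nnfdk simulate --family fourshape --n 64 --na 32 --i0 256 --seed 7 --hq --out walnutless
wrote dataset (N=64, Na=32, I0=256.0) to walnutless

$ nnfdk train --data walnutless --nh 4 --nt 30000 --nv 30000 --seed 7 \
        --out params.json --log training.csv
trained Nh=4 network on 1 dataset(s); best validation loss 0.7848; parameters -> params.json

$ nnfdk reconstruct --data walnutless --params params.json --out rec_nnfdk.tiff
$ nnfdk fdk --data walnutless --filter hann --out rec_fdk.tiff

$ nnfdk evaluate --rec rec_nnfdk.tiff --ref walnutless/hq_target.tiff --metrics tse,ssim
metric,value
tse,2.281092e-05
ssim,0.98013882

$ nnfdk evaluate --rec rec_fdk.tiff --ref walnutless/hq_target.tiff --metrics tse,ssim
metric,value
tse,0.00014771593
ssim,0.78277704
```

The test-set error (TSE) is half the mean squared difference to the
reference over the region of interest around the object; SSIM is the
structural similarity with a uniform 19-pixel window.  At this noise
level the learned four-filter combination reduces the TSE by ~6x and
raises SSIM from 0.78 to 0.98 relative to plain Hann FDK — noise is
suppressed while object structure is retained.  Other subcommands:
`nnfdk sirt` (SIRT⁺ baseline), `nnfdk fixture` (self-consistent test
scenes).

The same pipeline is available as a library: see
`nnfdk.experiments.fourshape_noise_experiment`, which trains one NN-FDK₄
network on 10 random Fourshape datasets and evaluates it against
Hann-FDK on 10 fresh phantoms (at `N = 64`, `Na = 32`, `I0 = 256` it wins
on 10/10 with a ~1.8x mean TSE advantage against the ground truth).

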