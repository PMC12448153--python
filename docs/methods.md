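# Methods

## Model

The package segments 2D grayscale image slices (the motivating setting is
T2-weighted prostate MRI, with background / transition-zone / peripheral-zone
labels) with a conditional random field whose potentials are computed by
learnable functions of deep image features.

The label field `X = {x_ij}` over an `H x W` grid, conditioned on
observations `O`, follows a Gibbs distribution

    P(X = x | O) = exp(-E(x | O)) / Z(O),
    E(x | O) = sum_ij psi_u(x_ij | O)
             + sum_{((i,j),(i',j')) in E} psi_b(x_ij, x_i'j' | O),

on a graph whose edges connect each pixel to its 8 nearest neighbours
(Chebyshev distance 1, truncated at image borders).  The 8-neighbour graph
captures axis-aligned and diagonal boundary geometry at a small fraction of
the cost of a fully connected CRF.  The partition function `Z` is never
evaluated by the method; it exists only inside the exact-enumeration oracle
used for testing (`graph.exact_marginals`).

Inference and training proceed in three phases:

1. **Features.**  A U-Net-style encoder--decoder (`backbone`) maps the image
   to per-pixel deep features `F in R^{H x W x C}`.  Filters double per
   resolution level; the decoder mirrors the encoder with skip connections;
   instance normalisation and ReLU follow every convolution.  Any feature
   extractor with the same contract can be plugged in.
2. **Potentials.**  The unary potential is an affine map of the pixel's
   feature vector (a linear layer, `C -> K`).  For the pairwise potentials,
   a sinusoidal positional encoding is added to the features
   (`o' = o + PE`), a shared two-layer MLP `f` re-embeds each pixel
   (`phi = f(o')`), and for every edge a second two-layer network `g` maps
   the elementwise squared difference `d(phi_p, phi_q)` to `K^2` logits:
   `M = exp(g(d))`, a strictly positive `K x K` cost matrix.  Because `d`
   is symmetric, both directions of an edge share one matrix; a message
   travelling against the stored orientation uses its transpose.
3. **Inference.**  Approximate mean-field: `Q` is initialised as
   `softmax(-psi_u)` per pixel and updated synchronously for `N` iterations
   (pseudo-potential accumulation from all in-edges, add the unary, softmax).
   The loop is unrolled through the package's autodiff engine, so the
   cross-entropy loss backpropagates through all `N` iterations into `g`,
   `f`, the unary head and the backbone — the model is trained end to end.

### Positional encoding convention

Channels come in groups of four, `(sin wj, cos wj, sin wi, cos wi)` for
group `k = c // 4`.  The frequency is the decaying transformer convention
`w = 10000^(-4k/C)`: the growing alternative `10000^(+4k/C)` produces
frequencies of order `10^4` radians per pixel, which alias on any practical
grid.  The growing form remains available behind `growing_frequency=True`
for comparison.

### Baseline pairwise potentials

Four classic variants share the same graph and inference loop:

- `spatial` — Potts compatibility (zero on-diagonal) weighted by a Gaussian
  kernel of pixel distance, `w * exp(-d^2 / 2 theta_s^2)`; axis-aligned
  edges couple more strongly than diagonal ones.
- `intensity` — the spatial kernel multiplied by
  `exp(-|I_p - I_q|^2 / 2 theta_i^2)`.
- `posterior` — as `intensity`, with the backbone's class-posterior vectors
  in place of raw intensities (differentiable through the unary head).
- `postproc` — the plain backbone is trained alone; the intensity-kernel
  CRF is applied only at prediction time.

Default bandwidths are `theta_s = 1` pixel and `theta_i = 0.1` in
normalised-intensity units, weight 1 — conventional values, exposed in the
config since no canonical setting exists for them.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| mean-field iterations `N` | 5 | more iterations change results marginally; 0 disables the CRF |
| feature width `C` | `base_filters` | must be divisible by 4 (positional-encoding groups) |
| `f` / `g` architecture | 2-layer MLP, hidden width `C`, ReLU | `g` outputs `K^2`, reshaped row-major |
| `g` logit clamp | ±30 | guards `exp` overflow; far outside the operating range |
| `g` final-layer init | He x 0.01 | `M` starts near `exp(0) = 1`, a constant matrix the per-pixel softmax cancels, so early training is unary-driven and the pairwise term grows in smoothly |
| learning rate | 1e-4 (`TrainConfig`) | the full-scale recipe (200 epochs); desk-scale experiments (`experiments.py`) use 1e-3 over 20 epochs, the standard small-model Adam rate |
| weight decay | 1e-5 | L2 added to the gradient |
| gradient clip | 0.01 | global-L2-norm clipping; per-value clipping behind `clip_mode="value"` |
| batch size | 8 | unconstrained by the method |
| gamma-augmentation range | [0.7, 1.5] | exponent applied to the slice's own min--max range, so it is monotone and identity at 1 even for z-scored data |

Normalisation is per patient: z-scoring for the primary contrast,
`[0, 1]` min--max rescaling for auxiliary channels.  Validation-based
checkpoint selection uses mean foreground Dice.

## Synthetic phantoms

`synthetic.generate_phantom` emulates the statistical structure the method
targets without any data download: per slice, an elliptical gland whose
interior splits into an anteriorly shifted TZ ellipse and the posterior
crescent remainder as PZ (so the PZ partially surrounds the TZ), intensity
means ordered background < TZ < PZ as on T2w, an ellipsoidal through-plane
profile so zones thin toward the apex and base, and background-only slices
beyond the gland extent.  Corruptions: additive Gaussian noise (sigma 0.05
by default; a Rician option exists), a smooth multiplicative bias field
(random second-order 2D polynomial, amplitude 0.15 by default, 0.4 in the
"corrupted" study arm), and a global per-patient intensity scale/shift
(±10%).  Default geometry is 64 x 64 pixels, 8 slices, voxel spacing
(3.0, 0.625, 0.625) mm.

What the phantoms do **not** model: anatomical shape variability beyond
ellipses/crescents, partial-volume boundaries, acquisition artefacts other
than bias/noise/shift, and real DWI/ADC contrast physics (multi-channel
phantoms are replicated contrasts).  Passing the phantom study therefore
demonstrates that the pipeline optimises, that the CRF head does not hurt
under the modelled corruptions, and that the machinery is correct — not
clinical-grade performance on real MRI.

## Desk-scale study sizes

The end-to-end experiment (`experiments.run_zonal_experiment`) uses 40
phantom patients split 30/5/5, a base-8-filter two-level backbone, `N = 5`,
20 epochs, batch 8, Adam at 1e-3 — sizes chosen so the whole study runs on
a single CPU in minutes (the phantom zones are driven by intensity and
position, so two resolution levels already cover the needed context).  At this scale the phantom task is nearly
saturated (test Dice > 0.99 for both zones), so variant comparisons are
read as "the learned CRF does not fall behind the plain backbone under
corruption" rather than as effect-size estimates.

## Evaluation

Metrics are 3D and per patient: Dice similarity (`2|P n G| / (|P| + |G|)`,
defined as 1 when both masks are empty), relative absolute volume
difference (`|V_p - V_g| / V_g`), and average symmetric surface distance in
millimetres.  ASSD boundaries are foreground voxels with at least one
face-adjacent background neighbour; distances are computed with
spacing-weighted Euclidean distance transforms, and the symmetric mean
weights the two directed averages by surface size.  The apex / mid-gland /
base breakdown takes, among slices containing any reference foreground
(the full acquisition would usually make apex and base empty), the first
two as apex and the last two as base; it requires at least five such
slices.

Lesion detection follows the free-response convention: 26-connected local
maxima of the probability map (minimum peak 0.1, minimum physical peak
separation 5 mm — unconstrained choices, exposed in config) are detections
ranked by peak value; a detection is a true positive when it lies within
5 mm of any reference lesion voxel; extra detections on an already-detected
lesion are ignored; sensitivity is reported at fixed
false-positive-per-patient allowances (0.5–3) by sweeping the rank cut.

## Numerical choices

- All softmaxes subtract the per-pixel maximum; per-pixel normalisers are
  never materialised standalone.
- Mean-field updates are synchronous, matching the unrolled-RNN view;
  early stopping on a Q-change tolerance exists but is off by default.
- The tensor engine (`autodiff.py`) is a reverse-mode tape over NumPy with
  exactly the primitives the models need; convolutions are GEMM-based
  (stride 1, NHWC), and the message-passing step is a single fused node
  with a hand-derived backward pass.  Gradient correctness of every
  primitive and of the fused nodes is pinned by central-difference tests.
- Float32 is the training dtype; float64 is used where tests compare
  against numerical differentiation.
- Degenerate inputs fail loudly: constant volumes cannot be normalised,
  empty reference volumes have no RAVD, empty surfaces no ASSD, and the
  exact-enumeration oracle refuses state spaces beyond ~2^20.

## Known limitations

- 2D slice-wise modelling only; no 2.5D/3D edge sets.
- The 8-neighbour graph cannot represent long-range dependencies directly;
  they arise only implicitly through the backbone's receptive field.
- The default backbone is a small generic U-Net, not a reimplementation of
  any specific published architecture; the feature-map contract is the
  intended extension point.
- Mean-field is a variational approximation: tests quantify its deviation
  from exact marginals only at weak coupling on tiny grids, where
  enumeration is possible.
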