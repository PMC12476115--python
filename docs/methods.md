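# Methods

## The model

`dynamap` frames dynamic brain-network mapping as spatiotemporal dense
prediction. A preprocessed scan `x ∈ R^{h×w×d×t}` is cut, frame by frame,
into non-overlapping `ps³` cubes; each cube is flattened and linearly
projected to an `e`-dimensional token, and a learnable positional
embedding of shape `(t, p, e)` is added (`p` tokens per frame). Two
encoder configurations are provided:

- **space–time**: all `t·p` tokens form one sequence and attend to each
  other jointly through `L` pre-norm transformer blocks
  (`z ← z + MHSA(LN(z))`, then `z ← z + MLP(LN(z))`; the MLP is two
  affine layers with randomized-leaky-ReLU activation and dropout);
- **sequential**: the token tensor is permuted to `(p, t, e)` and a
  temporal encoder attends over the `t` tokens at each spatial location,
  after which a spatial encoder attends over the `p` tokens within each
  frame. Embedding width is identical in both stages.

Attention is standard multi-head softmax attention; logits are scaled by
`√e_head` where `e_head = e / n_heads` is the per-head key width. The
decoder applies, per frame: layer norm → affine projection → addition of
a fixed sine-cosine encoding of the frame index (so frames with identical
content but different times decode differently) → reshaping tokens onto
the `(h/ps, w/ps, d/ps)` grid as `e` channel maps → three depth-wise
(groups = channels) transposed 3D convolutions with kernel sizes 7, 5
and 9, the last with dilation 2 → a point-wise (1×1×1) projection to the
`K` network channels with randomized-leaky-ReLU. Output is exactly
`(K, h, w, d, t)`.

Default hyperparameters for the full-scale configuration: embedding 96,
6 heads, depth 1, attention dropout 0.4, encoder dropout 0.3, patch
size 5; Adam with learning rate 0.01, weight decay 0.1, batch size 2, up
to 150 epochs with early stopping at improvement threshold 1e-5.

### Decoder stride/padding schedule

Only the kernel sizes and the final dilation are architectural
requirements; the stride and padding schedule is this package's choice.
Strides are (1, ps, 1): the middle convolution carries the entire ×ps
upsampling. Interior cropping equivalent to `ConvTranspose3d(padding=…)`
keeps every layer size-exact — layer 1 (k=7) crops 3+3, layer 2 crops or
pads its raw output `(g−1)·ps + 5` to exactly `g·ps`, layer 3 (k=9,
dilation 2) crops 8+8 — so feature maps never exceed the padded volume
size. This matters on CPU: without interior cropping the third layer's
maps would be ~40× larger than the target volume. Volumes not divisible
by `ps` are zero-padded at the high end before tokenization and
center-cropped on output.

### Randomized leaky ReLU

Negative slopes are drawn per element from U(1/8, 1/3) during training
and fixed at the interval mean (11/48) in evaluation mode, making
prediction deterministic.

## Weak supervision: windowed spatially constrained ICA

The data matrix of one window, `X ∈ R^{t_w×n}` (rows centered over the
`n` in-mask voxels), is modeled as `X = AS`. For each network `i` with
z-scored reference map `R_i`, the unmixing vector maximizes the
negentropy surrogate `(E[G(C_i)] − E[G(v)])²` with `G = log cosh` and `v`
standard normal, subject to unit variance and Pearson correlation
`φ(C_i, R_i) ≥ ε`. Implementation choices:

- `X` is whitened to the leading `m` principal components (`m` =
  number of references); estimation is deflationary in reference order,
  with Gram–Schmidt orthogonalization in whitened space.
- Each component runs the classic fixed-point (tanh) negentropy update.
  Whenever `φ < ε` after a step, the iterate is blended halfway with the
  reference's projection onto the whitened basis and renormalized — an
  adaptive penalty that realizes the Lagrangian constraint without a
  multiplier schedule.
- Initialization is the reference projection itself (deterministic);
  a seeded random direction is the fallback when the reference has no
  energy in the data subspace.
- `ε` defaults to 0.3. Components whose final correlation misses `ε`, or
  whose fixed point has not settled, are returned flagged
  `converged=False` rather than raising — infeasible references (e.g.
  orthogonal to the data) are a data property, not a programming error.
- Signs are fixed so `φ(C_i, R_i) ≥ 0`; mixing time courses are the
  least-squares regression of `X` on the recovered sources.

Windows of size 30 with stride 1 yield `⌊(t−w)/s⌋+1` overlapping
problems. To pair window-wise priors with the (temporally subsampled)
training frames, each frame takes the window whose center is nearest
(ties to the earlier window; frames outside the covered range clamp to
the nearest window with a warning). ICA runs on the full-length series
and subsampling happens afterwards, so windows always see contiguous
dynamics.

## Objective

For a prior/prediction pair the loss is
`mean(log cosh(y − ŷ)) / max(ε, SSIM(y, ŷ))`, averaged over the batch;
`ε = 0.001`. The photometric term is averaged (not summed) over voxels so
the scale is resolution-independent. SSIM uses global first/second
moments over each sample's full 4D tensor (a windowed 3D mode exists for
evaluation); stabilizers are `C1 = (0.01·R)²`, `C2 = (0.03·R)²` with `R`
the joint dynamic range of the two inputs, floored at 1 — the joint range
keeps the index symmetric, and the floor keeps the constants meaningful
for z-scored maps. When SSIM ≤ ε the clamp engages and the loss remains
positive and finite.

## Preprocessing

Frames are retained at indices 0, s, 2s, … (0-based; default stride 10,
10 frames), each retained frame is smoothed with a Gaussian kernel
(σ = 6 voxels by default, "nearest" boundary handling), and the 4D array
is z-scored with a single mean/std over all in-mask voxels and frames.
Global (not per-voxel) standardization preserves relative spatial
amplitude, which the SSIM term depends on; per-voxel standardization is a
config option. Z-scoring is idempotent, and smoothing conserves the
global mean up to boundary effects.

## Synthetic study conditions

The phantom generator emulates the statistical structure the model and
ICA assume, not the physiology: each network is an isotropic Gaussian
blob (σ = 2 voxels) whose center drifts linearly (default 1 voxel per
scan), modulated by a strictly positive sinusoidal amplitude waveform,
plus AR(1)-in-time, white-in-space noise (innovation σ = 0.2, lag-1
coefficient 0.3). Defaults place three networks on a 16³ grid for 60
frames. Populations draw per-subject center jitter (σ = 0.5 voxel) and
waveform scale jitter (10%); group 1 receives either a multiplicative
amplitude effect `(1 + effect_size)` inside a chosen region (an
"activity level" difference) or a zero-mean alternating modulation
(`effect_size · signal · cos(πτ)`) that changes temporal variability
while leaving the time average untouched for even `t`.

Blobs make every contract analytically checkable — recovery correlations,
aligned-prior fidelity, planted-effect sensitivity — but they lack
hemodynamic responses, physiological noise, scanner drift, multi-site
effects, and the spatial overlap structure of real ICA templates. Passing
tests therefore demonstrate correctness of the machinery under the
model's assumptions, not performance on clinical data.

## Evaluation metrics

- **mARE**: mean over voxels of `|y − ŷ| / (|y| + 1e-6)`.
- **mIOU**: each map binarized at its own 80th-percentile (in-mask)
  threshold; IOU of the suprathreshold sets, averaged over frames for 4D
  stacks. Two empty sets count as IOU 1. The percentile reading makes the
  metric invariant to monotone rescaling.
- **Hgt** (homogeneity): mean Pearson correlation between each ROI
  voxel's time series and the ROI-mean series; the ROI is the top-20%
  region of the reference map. Zero-variance voxels are excluded; a flat
  ROI-mean series yields 0.
- **Temporal gradient**: per-voxel sum of absolute forward differences.
- **Entropy trend**: Shannon entropy (bits) of each consecutive-frame
  gradient map, histogrammed into 256 equal-width bins over that map's
  own range (hence affine-invariant).
- **Blob density**: frames binarized at value ≥ 0.65 (maps are assumed
  z-scored or unit-max normalized); 3D connected components counted
  under 6-connectivity by default (corner-touching clusters count
  separately; 26-connectivity is a config option).

## Group statistics

Per-subject summaries (time-average or temporal-gradient maps) are
compared voxelwise with Welch's t-test — the safer default for unbalanced
cohorts; pooled variance is a flag. Benjamini–Hochberg FDR is applied
within each network map over in-mask voxels (per-network rather than
pooled, matching per-network result maps), and the display map is
`−log10(p)·sign(t)` zeroed where `q > α` (α = 0.05). Zero-variance voxels
report t = 0, p = 1. Swapping group labels negates t and the signed map
exactly.

## Numerical choices

- The network runs in float32 end to end; the autodiff engine preserves
  the dtype of its inputs (float64 in the gradient-check tests).
- The depth-wise transposed convolution evaluates via cached real FFTs
  (one forward FFT per operand, gradients reuse the spectra; the weight
  gradient is accumulated over frames in the frequency domain) and falls
  back to a direct tap loop when the problem is tiny.
- Gradients are clipped at global norm 1.0 — lr = 0.01 on batch size 1–2
  occasionally produces spikes early in training.
- Early stopping counts an epoch as a stall unless it beats the best
  epoch-mean loss by strictly more than the threshold; `patience`
  consecutive stalls stop training. No validation split is carved out by
  default (a split mode is available by config).
- Adam uses classic L2-style weight decay added to the gradient.
- All randomness flows through seeded `numpy` generators: same config,
  same machine ⇒ bit-identical training histories and predictions.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: 12³×60
phantoms for ICA (31–71 windows), one 16³×5 subject with a
16-dimensional, 2-head model for the 300-step overfit contract, and
10³-grid populations of 16–40 subjects for the group-statistics
calibration and power checks. These sizes were chosen so the full
pipeline — including both encoder configurations — completes in minutes
on a single CPU while keeping every contract quantitatively meaningful.

## Known limitations

- The phantom's realism gaps are listed above; no claim is made about
  clinical cohorts.
- Constrained ICA assumes stationarity within each window and degrades at
  low SNR — low-amplitude windows recover sources less accurately, which
  propagates into the aligned priors.
- One model predicts all networks as output channels (a per-network mode
  is a config flag); networks are not trained independently.
- No motion correction, registration, or slice-timing correction: inputs
  are assumed spatially normalized.
- Single-device training only; no mixed precision, no pretrained weights.
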