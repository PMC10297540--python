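# Methods

## The sub-band input framework

The package's premise is that a segmentation network sees cysts better when
its input channels separate an OCT B-scan into complementary frequency
content. Every transform here produces a `SubbandPyramid` — one decimated
low-pass band plus per-scale lists of directional detail bands — from which
two image-domain channels are built by *partial inverse reconstruction*:

* the **low-pass channel** inverts the pyramid with all detail bands
  zeroed (smooth layer anatomy, close to the original image);
* the **edge channel** inverts with the low-pass zeroed and takes the
  magnitude of the result, so boundaries read "bright" regardless of the
  sign of the intensity step.

Reconstruction rather than resized coefficient maps was chosen because it
keeps every channel pixel-aligned with the mask at full resolution — no
interpolation of decimated grids, and the two channels sum (before
magnitude/normalization) exactly to the input, which is a testable
invariant. Channels are min–max normalized per image so each input is
self-contained; dataset-level standardization was rejected because it
couples training images to each other.

Formations and their fixed channel orders:

| name | channels |
|---|---|
| `simple` | image |
| `{t}2` | `t_lp`, `t_hp` for one transform `t` |
| `combo4` | curvelet_lp, contourlet_lp, circlet_lp, dtcwt_lp |
| `combo5` | combo4 + contourlet_hp |
| `combo5hh` | curvelet_hp, contourlet_hp, circlet_hp, dtcwt_hp, contourlet_lp |

The transform order inside combinations is fixed (curvelet, contourlet,
circlet, dtcwt) so trained models are reproducible.

## The four transforms

All four share the same conventions: square power-of-two images on the
[0, 1] intensity scale, periodic boundary handling (natural for the
FFT-based constructions and what makes the perfect-reconstruction
statements exact), row-major coordinates, and a geometry header sufficient
to invert a stored pyramid.

**Contourlet.** A Laplacian pyramid with the CDF 9/7 biorthogonal scaling
filters (analysis low-pass normalized to DC gain 1, interpolation filter to
DC gain 2, so constants pass through exactly) followed by a directional
filter bank per band-pass residual. The DFB is implemented in the frequency
domain: smooth wedge windows on orientation mod π that form an exact
partition of unity, so the directional bands of a level sum back to the
residual to machine precision. Default directions are [4, 8, 8]
coarse→fine. The pyramid is perfectly reconstructing by construction (each
level stores the true prediction residual), independent of filter choice.

**Dual-tree-style complex wavelet.** Six complex oriented bands per dyadic
scale, centred at 15°…165° in 30° steps. The analytic behaviour of a
dual-tree filter pair is realized spectrally: amplitude partition-of-unity
radial (square-annulus) windows × six angular windows × a half-plane
factor that restricts each band's support to one frequency half-plane
(self-conjugate rows weighted ½ so the conjugate halves still sum to one).
Coefficient magnitudes are then nearly shift invariant — under a 1-px
circular shift, band energies are invariant to round-off — while
reconstruction (twice the real part of each band, plus the low-pass) is
exact. This frequency-domain construction was chosen over spatial q-shift
filter banks because it gives the same invariants (6 oriented complex
bands, PR ≤ 1e-8, shift-stable magnitudes) with no dependence on tabulated
filter coefficients.

**Curvelet.** An FFT tight frame: square-annulus radial windows times
angular wedges whose *squares* sum to one, with the angular count doubling
every other scale from coarse to fine (parabolic scaling; default 8 wedge
pairs at the coarsest scale). Wedges are paired with their antipodes so all
coefficients of real images are real — downstream channel construction
needs no complex handling. Because the frame is Parseval, total coefficient
energy equals image energy exactly and the adjoint is the inverse. Detail
bands are kept at full resolution (only the low-pass, whose support is an
exact sub-grid, is decimated by spectral cropping); this trades redundancy
for simplicity and exactness.

**Circlet.** `n_rings` concentric raised-cosine radial windows (Euclidean
radius, outermost ring covering the spectrum corners) that sum to one, so
the bands sum back to the image — the inverse is literally addition. A pure
radial sinusoid whose frequency sits at a ring centre lands ≥ 90% (in
practice ~100%) of its AC energy in that ring.

Numerical notes: all windows derive from the C³ polynomial step
ν(t) = t⁴(35 − 84t + 70t² − 20t³) with ν(t) + ν(1−t) = 1; angular windows
are explicitly symmetrized under FFT-grid negation because the sampled
Nyquist rows break the analytic θ-mod-π symmetry (without this the
curvelet's real-coefficient convention would leak ~1% of energy). Low-pass
decimation uses centred spectral cropping, which is lossless because the
windows vanish outside the cropped sub-grid. Decomposition depth defaults
to 3 scales (2 for images ≤ 64 px), with every decimated band kept ≥ 2×2.

## Denoising

High-pass sub-bands can be soft-thresholded before reconstruction:
`sign(x)·max(|x|−λ, 0)`, complex coefficients shrunk in magnitude with
phase preserved. λ defaults to the universal threshold σ̂·√(2 ln N) with
σ̂ = median(|band|)/0.6745, which removes > 99.9% of pure-Gaussian band
energy while shrinkage never increases any coefficient magnitude. When
enabled, denoising is applied to clean and noisy inputs alike — the
formation, not the input, decides.

## Noise model

Stored B-scans are treated as already log-transformed (the display domain
in which device speckle is approximately additive), so robustness is probed
with additive white Gaussian noise. σ is quoted on the 0–255 8-bit scale
(protocol default 80, i.e. σ ≈ 0.314 on the unit scale) and the dataset
protocol replaces a seeded 70% of images with noisy versions. SNR is the
Frobenius energy ratio in dB, computed on the unclipped additive model.

## Metrics, loss, conventions

Dice, Jaccard, sensitivity % and false-positive-ratio % all derive from
integer confusion counts; the identity J = D/(2−D) holds exactly. The
Tversky index `TP/(TP + α·FN + β·FP)` is computed without smoothing on
integer counts (0/0 → 1 by the both-empty convention); the *soft* variant
used as the training loss pools probability-weighted counts over the batch
with ε = 1e-6 smoothing. α = 0.8, β = 0.2 penalizes missed cyst pixels
four times as hard as false alarms — appropriate when the foreground is a
few percent of pixels. Predictions binarize at 0.5. An empty truth mask
makes Sen (and an all-positive truth makes FPR) undefined and raises rather
than returning a sentinel.

## Network and training

The segmentation model is a compact encoder–decoder written directly in
numpy with explicit backpropagation: per stage two 3×3 convolutions + ReLU,
2×2 max pooling between stages, nearest-neighbour upsampling with skip
concatenations on the way up, and a 1×1 convolution + sigmoid head. An
optional single-head self-attention block over the coarsest feature grid
provides the global-context pathway of a transformer-bottleneck U-Net; it
is off by default at desk scale. Optimization is Adam on the soft Tversky
loss, fully seeded (init, shuffling) so experiment reruns are byte-
identical. Gradients were verified against central finite differences to
~1e-8 relative error.

Reference full-scale defaults are kept in `TrainConfig` (filters
(8, 16, 32, 64, 128), Adam 1e-4, 150 epochs, fixed — no early stopping);
the desk-scale regime used by the tests and the acceptance script is
64-px phantoms, ≤ 64 images, filters (4, 8, 16), learning rate 1e-3 and
≤ 200 epochs, sized to run on one CPU in minutes. The experiment runner
trains each formation with the shared configuration and seed, evaluates
per-image metrics on the 80/20 split (the 20% split serves as validation;
there is no third partition), and writes a fixed-format CSV so reruns are
byte-identical.

## The phantom generator

A phantom is: a stack of horizontal layers (one deliberately thick, bright
host layer) with smooth sinusoidal vertical undulation, multiplicative
Gaussian-smoothed texture as a stand-in for speckle, and non-overlapping
dark ellipses (the cysts) placed entirely inside the host layer; the mask
is the exact analytic union of the ellipses. Defaults: 128 px (64 in
tests), 5 layers, 1–3 cysts of 3–10 px radius, 85% intensity drop, 25%
texture contrast. This captures what the formations exploit — smooth
regional structure vs. hypo-reflective blobs with sharp boundaries — and
deliberately *not* clinical realism: no shadowing, no depth-dependent
signal roll-off, no device-specific speckle statistics, no pathology
variety. Passing tests therefore demonstrate that the pipeline is correct
and that the formations behave as designed, not that any particular Dice
level transfers to clinical data.

Augmentation applies seeded rotation/shift/crop combinations identically to
image and mask (masks re-binarized after interpolation), and redundant
augmented images can be dropped greedily by SSIM (7×7 Gaussian window,
first-kept order, threshold 0.95 by default).

## Known limitations

* The curvelet keeps detail bands undecimated: memory is
  O(levels × angles × N²), fine at ≤ 512 px but not a wrapped FDCT
  replacement for large images.
* The frequency-domain DTCWT analogue shares the invariants of a spatial
  dual-tree implementation but not its filter impulse responses; coefficient
  values are not interchangeable with q-shift implementations.
* Training at desk scale (tens of images, tiny filter ladders) measures
  directional effects — e.g. that σ = 80 noise degrades validation Dice —
  with high variance on the 20% split; absolute metric levels are not
  comparable to full-scale GPU results on real datasets.
* Periodic boundary handling means an intensity step across the image
  border is a real edge to every transform; inputs are expected to be
  padded/framed accordingly (`pad_to_pow2` records the crop window).
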