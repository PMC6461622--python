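# Methods

## Flow model

At each slow-axis location the acquisition captures N consecutive B-scan
frames `I(x, y_i, z)` (linear intensity, i = 1…N in acquisition order).
Three per-pixel images are computed:

* mean image `I_s = (1/N) Σ_i I_i` — frame averaging suppresses background
  noise in the structural image;
* inter-frame speckle contrast
  `K_s = (1/(N−1)) Σ_{i=1}^{N−1} |I_{i+1} − I_i| / (I_{i+1} + I_i + ε)` —
  the normalised first difference over *consecutive* frame pairs.  Each
  term lies in [0, 1] for nonnegative intensities, so K_s does too.  A pair
  with zero denominator contributes 0 (a pixel dark in both frames carries
  no flow evidence); ε ≥ 0 (default 0) optionally regularises the
  denominator against detector noise at dark pixels;
* flow image `I_flow = I_s · K_s` — masking the mean image with the
  contrast image suppresses static tissue and preserves flow signal.

Assumptions: intensities are **linear** magnitude, not log-compressed.  The
ratio in K_s is invariant under a global intensity scale on linear data,
and log data would break the [0, 1] bound, so volumes carry an explicit
`intensity_scale` tag and log-scaled input is rejected rather than
converted silently.  K_s is order-sensitive (consecutive pairs), but
invariant under frame-order reversal (tested).  No inter-frame motion
registration is applied by default; an optional rigid x–z alignment by
phase cross-correlation is available (`register="rigid"`) for acquisitions
with bulk motion.

## Spectral reconstruction

The optional FD-OCT front end converts raw interferograms to structural
frames: background subtraction (explicit source spectrum, or the mean over
A-lines when absent), linear interpolation onto a uniform wavenumber grid,
dispersion compensation, optional Hann apodisation (off by default, since
windowing changes peak widths), and the magnitude of the per-line Fourier
transform with the single-sided half kept (`n_depth = n_spectral_pixels/2`).

Dispersion is the minimal two-coefficient polynomial phase
`exp(i(a2·k̄² + a3·k̄³))` on the centred normalised wavenumber k̄ ∈ [−1, 1];
compensation multiplies by its conjugate.  The normalised basis keeps a2/a3
magnitudes instrument-independent.  Sensitivity roll-off is hardware
characterisation and is not modelled.

## Quantification

The flow volume `(location, x, z)` becomes a VAD statistic through six
steps, in order:

1. **en-face projection** — maximum-intensity projection over the
   configured depth range (default: full depth).  Max projection is the
   standard OCTA choice for capillary visibility; mean projection is
   available but dilutes sparse in-column flow signal.
2. **gray-level normalisation** — linear rescale anchoring the 99th
   percentile to 1.0, clipped to [0, 1].  Percentile anchoring is robust to
   hot pixels and makes acquisitions with different overall brightness
   comparable; an all-zero image passes through unchanged.
3. **grayscale morphological smoothing** — opening-then-closing with a disk
   of radius 1 applied to the gray levels, *before* thresholding.  Per-pixel
   speckle makes the in-vessel en-face intensity distribution very broad;
   without smoothing a global histogram threshold lands inside the vessel
   class and under-segments heavily.  After smoothing the histogram is
   near-bimodal and automatic thresholding separates vessel from
   background.
4. **binarisation** — Otsu's threshold on the image histogram by default,
   or a fixed threshold; strictly `pixel > threshold`, so ties count as
   noise (documented for bit-exactness).  Otsu on a constant image is an
   explicit error directing to the fixed threshold.
5. **binary cleanup** — opening-then-closing of the mask with the same disk
   (removes isolated speckle pixels, bridges 1-px gaps); `none` is the
   identity.
6. **VAD and masking** — `VAD = vessel pixels / total pixels`, and the
   smoothed angiogram multiplied by the binary mask gives the final display
   image.

VAD is monotone non-decreasing as a fixed threshold decreases, and adding
vessel pixels never decreases it (both property-tested).

## Synthetic phantom

The phantom emulates exactly the physical premise the contrast statistic
exploits.  Fully developed speckle: each voxel has a circular complex
Gaussian amplitude g with E|g|² = 1, so noiseless intensity
|g|²·reflectivity is exponential with the stated mean.  Static voxels reuse
one amplitude draw across all N repeats; vessel voxels renew it between
consecutive frames by `g_{i+1} = √(1−ρ)·g_i + √ρ·g_new`, so ρ ∈ [0, 1] is
the fraction of speckle power renewed per frame.  Additive Gaussian
intensity noise (std `noise_sigma`, clipped at zero) is drawn fresh per
frame everywhere.  Vessels are tube segments rasterised by Euclidean
distance to the axis, so truth masks are exact: no point-spread blurring or
shadowing is modelled.  All randomness flows from one integer seed through
numpy's PCG64 (`np.random.default_rng`), giving bit-reproducible volumes.

Limit cases anchor the model: ρ = 0 with zero noise yields identical
repeats and K_s ≡ 0; ρ = 1 yields i.i.d. exponential consecutive
intensities, for which E|a−b|/(a+b) = 1/2 exactly ((a−b)/(a+b) is uniform
on [−1, 1]); the in-vessel mean contrast matches an independent Monte-Carlo
estimate of that constant in the tests.

**Reference phantom** (fixed recipe used by the end-to-end tests and the
acceptance script): 64 locations × 64 A-lines × 64 depth samples, 4 repeats
per location, three tubes along the fast axis of radii 2, 3 and 4 voxels at
distinct rows and depths (the middle one with a gentle axial slope),
ρ = 0.8, equal tissue and vessel reflectivity 1.0, noise σ = 0.1 (SNR ≈ 10).
This size keeps a full render-process-quantify cycle around a second while
leaving ~4,100 en-face pixels and ~5,700 vessel voxels for stable
statistics.

### What the phantom does and does not show

Passing the end-to-end recovery checks (Dice ≥ 0.7 against the truth
en-face mask, VAD within 25% of the true vessel fraction) demonstrates that
the processing chain is internally consistent and that its statistic
responds to speckle decorrelation as designed.  The phantom omits lateral/
axial PSF correlation between voxels, vessel shadowing, bulk motion,
attenuation with depth and multiple scattering, so these bounds say nothing
quantitative about accuracy on real tissue; in particular real VAD values
depend strongly on the (instrument- and protocol-specific) threshold and
morphology settings.

## Numerical choices and degenerate inputs

* 0/0 pairs in K_s contribute 0; ε defaults to 0.
* Frame stacks, mean/contrast/flow images and flow volumes are plain numpy
  arrays validated at function entry; acquisition-level containers
  (protocol, volume, en-face image, mask, configs, results) are dataclasses
  with invariant checks in `__post_init__`.
* TIFF stacks are written location-major / repeat-minor (all repeats of
  location 0 first), matching acquisition order; every volume file carries
  a YAML sidecar with the full protocol, intensity scale and dtype, and
  readers fail on any inconsistency instead of guessing.
* Depth cropping (`crop_top`) can exclude zero-delay/DC artifact rows
  before processing; default 0.
* The disk footprint of radius 1 is the 3×3 cross; squares keep their
  interior but lose single corner pixels under opening — large structures
  survive exactly only when compatible with the footprint shape.

## Known limitations

* The quantification defaults (max projection, 99th-percentile anchor,
  Otsu, disk radius 1) are documented choices; absolute VAD values are
  sensitive to them, so cross-study comparisons require identical settings
  (the CLI report embeds the full resolved configuration for provenance).
* Automatic (Otsu) thresholding still under-segments dim vessel edges by
  roughly 15–20% of the vessel area on the reference phantom; Dice overlap
  is high (~0.9) because the error sits at single-pixel boundaries.
* The rigid registration option corrects integer x–z shifts only.
* Phase-based flow estimators (phase variance, split-spectrum
  decorrelation, optical microangiography) are out of scope.
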