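# Methods

## Problem setting

A metal object inside the scanned field of view — here the metal stack
of an ultrasound transducer resting on the anterior chest wall —
corrupts CT reconstruction in two ways. Beam hardening: the
polychromatic X-ray beam loses its low-energy photons preferentially in
dense material, so line integrals through metal are underestimated and
the filtered back projection (FBP) develops dark shading and dark/bright
streaks between dense structures. Photon starvation: almost no photons
survive centimetres of metal, so those projection bins are dominated by
Poisson noise that the ramp filter amplifies into fine streaks. Both
mechanisms corrupt the Hounsfield units (HU) that radiotherapy planning
converts into electron density, which is why the artifacts need to be
removed rather than merely tolerated.

## Correction model

The corrupted slice is forward-projected into a parallel-beam sinogram
and the bins shadowed by metal are treated as missing data
(inpainting). Plain per-view linear interpolation across the metal
trace is known to re-introduce streaks wherever the interpolation path
crosses high-contrast anatomy (bone, lung boundaries); the normalized
variant divides the corrupted sinogram by the sinogram of a
piecewise-constant tissue prior first, interpolates the ratio (which is
≈ 1 and smooth where the prior is right), and multiplies back. The
quality of the correction therefore *is* the quality of the prior, and
the pipeline's two stages exist to produce a streak-free prior from a
streaked image:

1. **Stage 1** builds the prior directly from the corrupted slice:
   metal (≥ 2000 HU) and air (≤ −950 HU) are removed by thresholds,
   the remaining pixels are clustered into k = 3 tissue classes by
   one-dimensional k-means on HU, each class is painted with its
   cluster-mean HU, air is stamped back at −1000 HU, and metal pixels
   take the top cluster's value so the prior is smooth where
   interpolation happens. The metal trace is the forward projection of
   the metal mask, binarized, dilated by a disk of 2 sinogram bins
   (absorbing uncertainty in the metal threshold) and smoothed with a
   1-bin Gaussian; bins whose smoothed weight exceeds 5 % of the
   maximum are inpainted. FBP of the inpainted sinogram gives the first
   corrected scan.
2. **Stage 2** repairs what stage 1 could not: intense dark streaks
   near the metal are clustered as lung in the stage-1 prior and
   survive the first pass. Pixels where the first correction moved the
   image by more than 200 HU are reset to 0 HU, the result is
   re-clustered, and a single synchronous 3×3 majority vote reassigns
   each tissue pixel to the class holding the most window members
   (ties keep the current label; air/metal count as their own
   categories and are never reassigned). The stage-1 and stage-2
   clusterings merge as `initial + |spatial − initial|`: wherever they
   disagree the combined prior moves up from the initial value by the
   disagreement, lifting lung-mislabelled streaks toward soft tissue.
   The inpainting then repeats on the *original* sinogram with the
   combined prior and an undilated (smoothed-only) trace, since
   dilation blurs tissue adjacent to the metal.

The final scan averages the two corrections (fixed weights ½/½), adds
the unsharp-mask high-pass residual of the original scan
(σ = 1.5 px, zeroed inside the metal mask) to restore noise texture,
and copies the original pixels back inside the metal mask so the
transducer remains visible, mirroring how the evaluation transplants
those pixels into the reference.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `metal_hu` | 2000 HU (valid 2000–2500) | metal segmentation threshold |
| `air_hu` | −950 HU | air segmentation threshold |
| `k` | 3 | tissue clusters (lung / soft / bone) |
| `mask_size` | 3 | majority-vote window side (px) |
| `diff_hu` | 200 HU (valid 150–200) | residual-streak flag threshold between stages |
| `replace_hu` | 0 HU | value given to flagged pixels before re-clustering |
| `disk_radius` | 2 bins | trace dilation radius (stage 1 only) |
| `sigma` | 1 bin | trace Gaussian smoothing |
| `trace_threshold` | 0.05 | fraction of trace maximum that defines inpainted bins |
| `epsilon` | 10⁻² × mean positive prior projection | divisor floor in normalization |
| `highpass_sigma` | 1.5 px | noise-texture high-pass width |
| `filter_name` | ramp | FBP filter |
| `n_angles` | max(180, image width) | view angles over [0°, 180°) |

Projection uses parallel-beam geometry with the detector count equal to
the image width and support restricted to the inscribed circle; the
projected quantity is `HU + 1000` (air ≡ 0), an affine attenuation
surrogate that is legitimate because the normalization only ever forms
ratios of sinograms sharing the same convention. All sinograms of one
run share a single geometry object — the normalization division is
meaningless otherwise.

## Numerical choices

- **FBP filter.** Ramp (Ram-Lak) rather than an apodized kernel: on a
  256² slice the forward→FBP round trip has a self-RMSE of ≈ 12 HU with
  ramp versus ≈ 26 HU with Hann, and since the pipeline reconstructs
  the whole slice (not just the inpainted region), round-trip fidelity
  bounds the achievable quality everywhere. Hann remains available and
  is what the artifact simulator uses as its scanner-like kernel.
- **k-means initialisation.** Lloyd's algorithm from deterministic
  anchors at canonical tissue values (−800 / 40 / 700 HU, clipped to
  the observed range) for k = 3; evenly spread quantiles otherwise. On
  streaked slices a purely data-driven init can converge to a local
  optimum that splits soft tissue across two clusters (the streaks form
  a broad mode between lung and soft tissue), which destabilises the
  prior; the anchored init lands in the tissue-aligned basin for any
  noise realisation and makes the whole pipeline seed-independent.
- **Normalization guard.** The divisor is floored at 1 % of the mean
  positive prior projection. The floor matters only for rays that are
  essentially all air, but those bins anchor the linear interpolation
  across the trace at near-tangent views: with a vanishing floor their
  noisy ratios reach ±10³–10⁴ and, after interpolation and
  denormalization, drive the reconstruction to physically absurd
  values. One percent is still far below any ray that crosses tissue.
- **Tie-breaks and borders.** The majority vote is a single synchronous
  pass (all counts from the input map), windows are clipped at the
  image border, ties keep the current label when it is among the
  maximizers and otherwise fall to the first category in
  (tissue 0..k−1, air, metal) order.
- **Degenerate inputs.** An empty metal mask yields an empty trace and
  the pipeline reduces to a pure FBP round trip plus texture; a
  sinogram row fully covered by the trace is filled with its row mean
  (logged); clustering refuses images with fewer distinct HU values
  than k; non-square slices are air-padded (−1000 HU) to square for
  projection and cropped back.

## Synthetic study

The simulator exists to exercise the pipeline under controlled,
seedable conditions. The phantom is a 256² piecewise-constant thorax
slice (1.5 mm pitch): body ellipse of soft tissue (40 HU), two lungs
(−800 HU), heart (50 HU), spine and ribs (700 HU), air background
(−1000 HU), and a metal bar (3000 HU, 20 mm thick) just inside the
anterior surface whose width — 2 / 4 / 6 cm for the bundled
narrow/medium/wide fixtures — spans the realistic range of cardiac
transducer metal stacks, the dominant driver of artifact severity.

Corruption is produced by the two real mechanisms, in their minimal
form: a two-bin spectrum (weights 0.6/0.4) whose bins attenuate soft
tissue in ratio 1.2 (weighted mean 1, keeping tissue HU calibrated) but
metal in ratio 3 (beam hardening), and Poisson noise at I₀ = 10⁵
photons per ray with counts floored at one photon (photon starvation).
Per bin the scaled attenuation map is forward-projected in physical
units (μ_water = 0.02 mm⁻¹), attenuated by Beer–Lambert, summed over
bins, noised, log-transformed and reconstructed with a Hann-filtered
FBP. The defaults put the corrupted scans at a body RMSE of ≈ 82–95 HU
versus the reference, inside the severity band a clinical transducer
study reports.

What the model deliberately omits: scatter, detector crosstalk,
fan-beam geometry, anatomical texture, motion, and metal HU saturation
behaviour of real scanners. Passing tests therefore demonstrate that
the pipeline removes *hardening- and starvation-type* artifacts on
piecewise-constant anatomy; they do not certify performance on clinical
scans, where cluster structure is less clean and artifacts interact
with real texture.

## Evaluation protocol

Because the metal object exists only in the corrupted acquisition, its
pixels are transplanted from the corrupted scan into the reference
before scoring; SSIM (Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03)
and PSNR (20·log₁₀(PEAK/RMSE)) share the transplanted reference's
dynamic range (max − min) as PEAK, so corrupted and corrected rows are
directly comparable. HU restoration uses elliptical ROIs of ≈ 0.5 cm²
(23 px at 1.5 mm pitch, centre-in-ellipse membership) over heart, lung
and bone, compared per ROI with a two-sided paired t-test at α = 0.05
without multiplicity correction — each ROI is reported on its own.

Known limitations: the cluster-mean prior inherits a downward bias in
soft tissue wherever dark streaks join the soft cluster, so corrected
HU near the metal approaches the prior rather than the truth — the
correction halves the ROI error rather than eliminating it, and paired
differences can remain statistically detectable after correction. Edge
pixels of bone are partially assigned to the bone cluster, biasing the
bone prior slightly low. Both effects are inherent to prior-based
inpainting rather than implementation artifacts.
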