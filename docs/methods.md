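# Methods

## Scope and coordinate conventions

All analysis is 2D on maximum-projected fields. Coordinates are 0-based with
row = y, column = x, origin top-left. Physical quantities are in microns via
the configured pixel size (default 0.108 μm/px, a 60× sCMOS acquisition at
1×1 binning); every threshold that matters biologically (nucleus size,
activity distance) is specified in microns so the pixel size is a free
parameter.

## Registration

The sequential protocol's two passes share the DAPI counterstain. The
displacement of the RNA pass relative to the DNA pass is the argmax over a
search window of the cross-correlation of the two DAPI images,
C(Δx, Δy) = Σ A(x,y)·B(x+Δx, y+Δy), summed over the overlap.

Numerical choices:

- **Zero-mean peak search.** Raw cross-correlation of non-negative images is
  biased toward bright regions and large overlaps, so the estimator
  mean-subtracts both images over each overlap before summation
  (Σ a·b − Σa·Σb/N via four FFT correlations). The raw surface is still
  exposed (`cross_correlate`) and is checked against a literal direct-sum
  double loop in the tests.
- **Windowed search** (default 10% of the smaller image dimension):
  plate re-mounting shifts are small; windowing avoids spurious far peaks.
- **Integer displacement only**; at 0.108 μm/px the quantization error is an
  order of magnitude below the 1 μm activity threshold. No rotation, scale,
  or subpixel refinement.
- **Tie-break** at equal peak values: smallest |dx|+|dy|, then row-major
  order (minimal-motion hypothesis, deterministic); confidence is the peak
  over the best non-neighboring secondary peak, set to 1 on a tie.
- **Per-field estimation**: stage repositioning error is a per-field effect,
  so each field pair gets its own vector.
- Applying a vector: output(x,y) = b(x−dx, y−dy); exposed boundary pixels
  are exactly 0, so total intensity never increases. Registration applies
  the *negated* estimated vector to the RNA-pass channels, which lands their
  content on the DNA-pass frame (the round-trip invariant
  `estimate(a, apply(a, v)) = v` pins this convention down).

## Segmentation and QC

The built-in segmenter is deliberately classical — Gaussian smoothing
(σ = 2 px), Otsu threshold, hole filling, 4-connected labeling, removal of
objects under 50 px — because the simulator produces well-separated nuclei
and real deployments can import masks from any external segmenter as label
TIFFs. Touching-nuclei splitting is out of scope.

QC discards nuclei with equivalent circular diameter < 10 μm **or**
circularity 4πA/P² < 0.95. Two readings were open:

- *"smaller than 10 microns"* is read as equivalent diameter (a length,
  matching the unit); an area reading would carry μm².
- The filter is OR-across-failures (keep only nuclei both large enough and
  round enough): both conditions mark segmentation errors, and an
  AND-to-filter reading would keep tiny round debris.

Perimeter is measured as the length of the marching-squares contour after
Douglas–Peucker simplification at 1 px tolerance. Raw marching-squares
staircases overestimate curved perimeters by up to ~8%, which would push
rasterized disks below the 0.95 circularity gate; after simplification a
radius-50 disk measures ≈ 0.99 and an axis-aligned square ≈ 0.79 (analytic
π/4 ≈ 0.785). Circularity may slightly exceed 1 for small disks
(perimeter underestimation) and is not clamped. Border-touching nuclei are
flagged but kept unless `drop_border` is set.

## Spot detection

Diffraction-limited FISH spots are near-constant size, so detection is
single-scale: response = −σ²·∇²(G_σ∗img) with default σ = 2 px (≈ 0.22 μm
object scale at 0.108 μm/px). The Laplacian is the exact discrete 5-point
stencil applied to the Gaussian-smoothed image rather than a truncated
analytic LoG kernel; the discrete stencil sums to zero exactly, so constant
images give exactly zero response (detection is invariant to DC offset) and
the response of an interior blob telescopes to ~0 over the domain.

Candidates are pixels equal to their 3×3 neighborhood maximum with response
above threshold; candidates within 2σ of a stronger candidate are suppressed
(prevents double-counting one transcription site), with exact ties resolved
in row-major order, which also collapses response plateaus to their first
pixel. The threshold is an absolute response value, or per-image adaptive
(mean + k·sd of the response, default k = 5) when unset. Coordinates are
integer pixels; no Gaussian fitting or subpixel refinement.

## Radial position

Per field, the Euclidean distance transform of the binary nucleus mask gives
each nucleus pixel its distance to the nearest background pixel. Within each
nucleus the field is normalized by its maximum and subtracted from 1:
0 at the deepest interior point ("center"), 1 at the periphery. Pixels
8-adjacent to background are clamped to exactly 1 (the discrete transform
gives them distance 1 px, which would otherwise map to 1 − 1/max).
Degenerate nuclei with maximum depth ≤ 1 px map to 0 everywhere; QC removes
them anyway. The "center" is the distance-transform argmax, not the
centroid — these differ for non-convex nuclei, and the distance-transform
definition is the one implemented. Shells are [0,0.2), [0.2,0.4), [0.4,0.6),
[0.6,0.8), [0.8,1.0] — half-open with a closed top, partitioning [0,1]
without gaps or double counting.

## Allele accounting

Spots outside every nucleus are removed; per QC-passing cell, DNA and RNA
counts are binned "0"/"1"/"2"/">=3", and only cells with exactly 2 DNA and
≤ 2 RNA spots are analyzable (cells with more RNA spots are excluded
entirely, not truncated). Per DNA spot, the minimum 2D Euclidean distance in
microns over all RNA spots in the cell; no RNA in the cell → NA. Status:
NA → NoTranscription; distance < 1.0 μm (strict) → Active; else Inactive.
One RNA spot may validate both DNA spots when within the threshold of both —
no one-to-one matching is enforced. Group comparisons (KS) operate on
un-binned radial values; shells are for reporting only.

## Kolmogorov–Smirnov test

D = sup |ECDF₁ − ECDF₂| evaluated over the pooled sample. The two-sided
p-value is exact when n₁·n₂ ≤ 100 (configurable): all C(n₁+n₂, n₁) splits of
the pooled sample are enumerated vectorized, evaluating the ECDF difference
at the last pooled position of each tied run so ties are handled correctly.
Otherwise the asymptotic Kolmogorov distribution is used with the standard
effective-sample-size correction, p = Q((√eₙ + 0.12 + 0.11/√eₙ)·D) with
eₙ = n₁n₂/(n₁+n₂). Null calibration at n = 100 per group rejects at
α = 0.05 in ≈ 5% of trials.

## Synthetic plate simulator

The simulator emulates what the pipeline assumes about real data:

- **Nuclei**: non-overlapping disks or ellipses (radius range configurable)
  with a fixed 20 px border margin, independent of protocol, so a
  simultaneous and a sequential plate generated from the same seed share
  identical ground truth. DAPI is nucleus mask × (base + low-frequency
  random field); the texture gives cross-correlation structure to lock onto
  (flat disks are shift-degenerate along symmetry directions).
- **Alleles**: exactly two DNA spots per nucleus (diploid model); each is
  active with probability `p_active`; active alleles get one RNA spot within
  `rna_offset_max_um` (default 0.5 μm, uniform in the disk of that radius,
  constrained inside the nucleus). Spot positions follow either
  uniform-in-nucleus placement or a Beta(α, β) law on normalized radius
  (Beta(5,2), mean 5/7 ≈ 0.71, models a peripherally biased locus).
- **Separation guarantee** (on by default): the two DNA spots are at least
  max(4σ_psf + 2·offset, (1 μm + offset)/pixel + 2 px) apart and the
  inter-nucleus gap is at least 4σ_psf + 2 px, so (a) same-channel
  detections never merge and (b) an inactive allele can never fall within
  the activity threshold of its sibling's RNA spot — ground-truth activity
  is then exactly recoverable, which is what the recovery tests rely on.
  `rna_offset_max_um` must stay below 1 μm for the same reason.
- **Optics and camera**: spots are 2D Gaussians (σ = 2 px) on a constant
  background (the widefield max-projection PSF approximation); Poisson shot
  noise, then Gaussian read noise (σ = 50), rounded and clipped to the
  16-bit range. Default amplitudes (spots 2000, DAPI 800, background 200)
  give spot SNR well above 5.
- **Sequential mode**: the RNA pass (DAPI + RNA) is translated by
  `sequential_shift` (|shift| ≤ 16 px) and independently re-noised.
- **Determinism**: each (well, field) derives its generator as
  `default_rng([seed, well_index, field_index])`, so plates are bit-identical
  across runs and fields are independent of generation order.

What the simulator does **not** emulate: realistic chromatin texture, 3D
optics, spectral bleed-through, photobleaching, touching nuclei, cell-cycle
or ploidy variation (a stray-spot rate exists for negative-path testing
only). Passing the recovery tests therefore demonstrates the pipeline's
correctness under its stated assumptions — clean diploid geometry and
resolvable spots — not its robustness to crowded or aberrated real plates,
where segmentation and detection parameters must be tuned per plate.

## Problem sizes in the validation suite

Validation plates use a pixel size of 0.216 μm (the standard 2×2 camera
binning of the reference acquisition) with nuclei of 24–32 px radius
(10.4–13.8 μm diameter, above the 10 μm QC gate) in 300–360 px fields; all
thresholds are in microns, so the physics is unchanged while fields stay
small. The active-fraction study runs 3 transcription rates × 20 seeds ×
~500 cells (84 fields of 6 nuclei each); registration exactness uses 50
seeded 256 px fields with shifts up to ±15 px and Gaussian noise at 20% of
the DAPI foreground amplitude added independently to both copies of the
field. The KS exact branch is verified against an independent reference for
every sample-size pair with n₁·n₂ ≤ 100.

## Known limitations

- Integer-pixel registration: a true subpixel shift contributes up to
  0.5 px (≈ 0.05–0.1 μm) to every DNA–RNA distance.
- The activity threshold is a hard 1.0 μm cut; distances at the boundary
  flip class with 1 px localization error (the simulator's separation
  guarantee keeps validation away from the boundary by construction).
- The built-in segmenter assumes separated, convex-ish nuclei; crowded real
  plates need an external segmenter through the mask-import path.
- Exact KS enumeration grows combinatorially; above n₁·n₂ = 100 the
  asymptotic approximation is used, which is conservative for very small
  samples outside the exact regime.
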