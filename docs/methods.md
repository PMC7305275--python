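# Methods

## Timing model

The package models the detection delay of a 511-keV photon in a
scintillation crystal as the travel time to an exponentially distributed
absorption depth, truncated to the crystal length — the *photon travel
spread* (PTS).  Parameters, with units and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `L` | crystal length | mm | per experiment (10/20/40) |
| `beta` | linear absorption coefficient at 511 keV | mm⁻¹ | 0.087 (LYSO-like) |
| `c` | speed of light | mm/ps | 0.2998 |
| `T = L/c` | maximum travel time | ps | derived |
| `lam = beta·c` | absorption rate in time | ps⁻¹ | derived |
| `fwhm_add` | per-detector Gaussian jitter FWHM | ps | 0 |

`beta` is exposed everywhere and never hard-coded into results: the
effective absorption rate of a real detector stack depends on the
interaction mix and is not knowable from first principles here.  0.087 mm⁻¹
is the conventional LYSO attenuation value at 511 keV.

The coincidence difference of two independent truncated-exponential delays
is the CTR kernel f_D (closed pdf and CDF); its T → ∞ limit is the Laplace
density; per-detector Gaussian jitter of width σ each side adds a
difference-domain Gaussian of width √2·σ, giving the analytic convolution
kernel f_conv.  All four are exposed behind one contract (`pdf`, `cdf`,
`support`), which is exactly what binned TOF projection weights require.

### Blur conventions

`fwhm_add` is interpreted as the *single-detector* FWHM (the convention of
detector-level time-resolution settings); the induced blur on the time
difference has σ_diff = √2·fwhm_add/2.35482.  A flag
(`fwhm_is_difference=True`) switches to the difference-domain reading.

## Numerical evaluation

Naive forms of these kernels overflow at physically plausible parameters
(sinh/csch for large λT; exp(2λT) and exp(λ²σ²/2) in the convolution), so:

- f_D is evaluated as (λ/2)·e^{−λ|d|}(1 − e^{−2λ(T−|d|)})/(1 − e^{−λT})²
  — every exponent non-positive, exact via `expm1`.  The CDF's tail mass is
  e^{−λ|d|}·expm1(−λ(T−|d|))²/(2·expm1(−λT)²); at d = 0 this is exactly ½
  with no case split.
- f_conv is decomposed into four integrals of exp(∓λx) against the Gaussian
  over half-supports.  Each product e^m·Φ(±u) is computed through the
  scaled complementary error function, `erfcx`, with the combined exponent
  algebraically reduced to −sλx₀ − (x₀−d)²/2σ², which is bounded by ~λT for
  every term that occurs.  When both Gaussian arguments sit in the same
  tail the e^m terms cancel analytically and are never formed.  The raw
  closed erf form is kept as `conv_pdf_reference`, a cross-check oracle
  valid at moderate parameters; tests assert agreement with it and with
  brute-force numerical convolution to 1e-7.  Genuinely unrepresentable
  regimes (λT > 700) raise with the offending parameters.
- The convolution CDF is obtained by integrating the same four terms by
  parts, again with all boundary exponents ≤ 0.  Values within one double
  ulp of 1 are snapped to 1 so the far plateau is exactly monotone.
- Densities return 0 outside their support instead of raising — binned use
  in the projector stays branch-free.
- `kernel_fwhm` brackets the half-peak crossing on the right flank
  (symmetric unimodal kernels) and bisects to ~1e-12 relative; a coarse
  monotonicity scan rejects non-unimodal inputs.

The convolution kernel converges to a Gaussian of variance σ² + Var(f_D)
for σλ ≳ 10; the comparison in the tests is against that variance-matched
Gaussian, since against N(0, σ) the CTR's own variance leaves a ~10⁻³
relative gap at σλ = 10.

## Model comparison conventions

K-L distance is KL(empirical ‖ model) in nats; model masses are the kernel
CDF increments over the histogram edges, renormalised over the histogram
support.  Empty bins contribute zero; an occupied bin with zero model mass
yields +∞ (no epsilon fudging).  For scoring a *finite-support* kernel
against blurred data — whose tails the kernel cannot cover by construction
— a `support_only` variant renormalises both distributions over the bins
where the model has mass; without it that comparison is identically +∞ and
carries no information.

The boundary-optimised Gaussian fit sweeps symmetric boundaries ±b over bin
edges, fits a bin-weighted Gaussian MLE inside each b, scores it by K-L
against the full histogram, and keeps the arg-min (ties to larger b).
Under this rule the optimal boundary for pure-PTS data is essentially the
full range at every opacity tested (λT up to 12): clipped Gaussians assign
near-zero mass to occupied shoulder bins and are heavily punished.  Strong
boundary clipping of the kind seen on measured detector data requires a
spiked-core response (e.g. from Compton interactions), which this simulator
deliberately does not model.  The bounded fit therefore reduces to the
unbounded one here, and the tests assert the K-L ordering (bounded ≤
unbounded) and true-Gaussian self-consistency rather than an FWHM gap.

λ is estimated by bounded 1-D maximum likelihood on the stable log-density,
seeded by matching the closed-form variance 2·Var_truncexp; σ of the
convolved kernel likewise by bounded MLE with σ ≥ 10⁻³ ps (idealised data
collapse to that floor).

## What the simulators emulate — and what they do not

`timing_sim` reproduces exactly the two-crystal PTS experiment the kernels
assume: perpendicular incidence, truncated-exponential depths, optional
Gaussian jitter.  `scan_sim` reduces the cylindrical scanner to a single
2-D ring (radius 424.5 mm, 666 detectors of 4×4 mm² faces with 0.2-mm
gaps, 4.1-ns coincidence window, 1-ps TOF bins, minimum detector
difference 83, all rescalable), generates true coincidences only from
piecewise-constant disc phantoms, and assigns detectors by angular sector
with optional gap rejection.  Effective LOR endpoints sit at ring radius
plus an average depth-of-interaction constant (3.6/5.8/7.4 mm for
10/20/40-mm crystals, configurable).

Not modelled: Compton interactions and inter-crystal scatter, oblique
path-length corrections, energy resolution and windowing, attenuation
(neither simulated nor corrected, keeping the CRC contract consistent),
scattered and random coincidences, axial physics, optical-photon transport
and pulse formation.  Consequently, passing tests show that the
*procedures* behave as the theory predicts under the PTS model; they say
nothing about instrument-specific numbers (fitted FWHM values, absolute
K-L of Gaussian fits, average DOI of a full physics simulation), which
depend on exactly the physics excluded here.

## Reconstruction

TOF list-mode MLEM on a square 1-mm voxel grid.  Per event, the weight of
voxel j is p_ij·K_it;j with p_ij the exact Siddon intersection length of
the effective LOR and K the kernel CDF increment over the event's 1-ps TOF
bin, evaluated at the voxel centre's signed projection v′ = 2s/c onto the
TOF axis (positive towards detector b; an annihilation displaced towards b
makes delta_t = t_a − t_b positive — fixed once and unit-tested with an
off-centre point source).  These weights are iteration-independent and are
assembled once into a sparse matrix (events sharing a detector pair reuse
one ray trace; weights below 10⁻¹⁴ of the row maximum are dropped), making
each of the 60 default iterations two sparse mat-vecs.  The sensitivity
image is the non-TOF backprojection over all admissible pairs — TOF
weights telescope to one over a full window.  No subsets, no
post-smoothing, no priors.  The update preserves non-negativity, never
decreases the list-mode Poisson log-likelihood, and satisfies the fixed
point Σ_j s_j x_j = number of used events after every iteration (all three
asserted in tests).

## Figures of merit

CRC = (μ_H/μ_B − 1)/(α − 1) with α = 4.5 and μ_B pooled over background
ROIs; peak-to-valley = mean image value at rod centres over mean at
valleys (midpoints of nearest-neighbour rod pairs — the valley definition
is a package choice); cog-ratio = value at the ROI's intensity centroid
over the ROI mean (< 1 flags a ring-shaped edge artefact).  A voxel belongs
to a disc ROI iff its centre lies inside.  All three are invariant under
global image scaling.

The 2-D NEMA-IQ section places the four hot discs (10/13/17/22 mm, 4.5:1
contrast) every 90° on a 25-mm ring inside a 60-mm background disc;
background ROIs of each sphere diameter sit on the 45° diagonals at 34 mm,
the closest ring at which the largest background disc clears every hot
disc.  The Derenzo-style phantom packs six 60° wedges of rods
(7/5/4/3.5/3/2.5 mm, spacing twice the diameter) in a 50-mm disc over a
warm background (rod:background 4:1).

## Desk-scale experiment designs

Chosen once, as this package's study conditions:

- **Kernel agreement (headline check):** 5×10⁶ idealised differences per
  crystal length at the default β, λ refitted by MLE, K-L on 1-ps bins.
  The sampling floor is ≈ (bins−1)/2n ≈ 10⁻⁵–10⁻⁴, far under the 8×10⁻⁴
  bound.
- **Blur sweep:** L = 20 mm at λT = 2.8 (β = 0.14 mm⁻¹ — the sweep's
  stated opacity; the default β gives λT = 1.74, where the Gaussian curve
  is additionally non-monotone at the smallest blur step), 2×10⁶ events per
  FWHM_add ∈ {0…100} ps.  The Gaussian fit's K-L decreases with blur until
  it reaches the sampling floor, which itself grows with histogram width;
  the test reads the curve floor-aware.  The bare CTR kernel's K-L
  (common-support) increases throughout; the two curves cross exactly
  once; the fitted convolution kernel is minimal everywhere.
- **NEMA CRC:** 40-mm crystal (largest pure-PTS Gaussian mismatch:
  unbounded-fit FWHM 99 ps vs CTR 53 ps), 180 detectors, 128² grid at
  1 mm, 4×10⁵ events, 60 iterations.  CRC grows with sphere diameter;
  the matched CTR kernel is not beaten by the unbounded-Gaussian fit
  beyond a ±0.02 statistical tolerance (the seed-to-seed spread at this
  event count — the systematic matched-kernel advantage reported at
  hundred-fold larger 3-D studies is below this floor); a grossly
  mismatched Gaussian (4× the CTR FWHM) overshoots CRC above 1 through
  edge artefacts.
- **Derenzo:** 10-mm crystal, 3×10⁵ events.  On the full 666-detector ring
  the PSF is sharp enough that ring artefacts form in the 7-mm rods: the
  centre-of-gravity ratio rises over early iterations, then dips, with the
  matched CTR kernel retaining a higher ratio than the over-wide Gaussian
  at late iterations.  Peak-to-valley ordering across rod sections is
  evaluated on a 360-detector ring, where resolution is blur-limited and
  the ordering is strict; on the 666-detector ring the same artefacts that
  drive the cog dip also depress section A's peak-to-valley, so the
  ordering is not monotone there.

## Known limitations

- The bounded-Gaussian boundary search cannot reproduce spiked-response
  clipping (see above) — a property of the data model, not the optimiser.
- The 2-D ring with sector-centre detector assignment adds a transaxial
  discretisation blur absent from the timing model; it affects all kernels
  identically but dilutes kernel-mismatch effects at low detector counts.
- CRC comparisons at 4×10⁵ events carry ~±0.02 noise; conclusions finer
  than that need repeated runs (every generator is seeded for exactly this
  purpose).
- The convolution CDF loses ~2 significant digits when σ ≫ T from
  cancellation between half-support terms; irrelevant at the tolerances
  used here but visible below 10⁻¹⁰.
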