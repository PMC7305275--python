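# tofpet — non-Gaussian time-of-flight kernels for ultra-fast PET

Time-of-flight (TOF) PET scanners localise each annihilation along its line
of response (LOR) from the arrival-time difference of the two 511-keV
photons (≈ 2 mm per ps).  Reconstruction conventionally models that timing
response with a Gaussian kernel.  At ultra-fast timing resolutions this
breaks down: the dominant residual spread is the *photon travel spread*
(PTS) — each photon penetrates an exponentially distributed depth into its
scintillation crystal before being absorbed, so its detection delay follows
a truncated exponential, and the coincidence difference follows a sharply
peaked, finite-support kernel rather than a bell curve.

This package is for detector and reconstruction researchers who want to
study that regime at desk scale: it provides the closed-form timing
kernels, a Monte Carlo coincidence simulator, model-comparison machinery,
and a 2-D TOF list-mode MLEM reconstructor that can apply any of the
kernels, together with the standard image-quality figures of merit.

## The model

A photon entering a crystal of length *L* (mm) with absorption coefficient
*β* (mm⁻¹) is absorbed at depth *x* with density ∝ exp(−βx) truncated to
[0, *L*].  In time units (λ = βc, T = L/c, c ≈ 0.2998 mm/ps) the absorption
delay has density

    g(t; λ) = λ e^{−λt} / (1 − e^{−λT}),  0 ≤ t ≤ T.

The coincidence time difference d = t_A − t_B of two independent such
delays — the *CTR kernel* — is

    f_D(d; λ) = λ sinh(λ(T − |d|)) csch²(λT/2) / 4,   |d| ≤ T,

with a closed-form CDF, tending to the Laplace density (λ/2) e^{−λ|d|} as
T → ∞.  Additional per-detector Gaussian jitter of width σ (photodetection,
electronics) turns the kernel into the analytic convolution f_D ⊗ N(0, σ²),
implemented here through scaled complementary error functions so that no
intermediate overflows even for very opaque crystals or wide blur.

Reconstruction uses TOF list-mode MLEM: the per-event weight of voxel *j*
factorises into the geometric intersection length p_ij (Siddon ray tracing)
and the kernel mass falling into the event's 1-ps TOF bin,
K = cdf(k_{t+1} − v′) − cdf(k_t − v′), where v′ is the voxel centre
projected onto the TOF axis.  Contrast recovery (CRC), peak-to-valley
ratios of a Derenzo-style rod phantom, and the centre-of-gravity/ROI-mean
ratio (an edge-artefact indicator) evaluate image quality.

## Worked example

Simulate idealised coincidence timing for the three crystal lengths, fit
the analytic CTR kernel (absorption rate by maximum likelihood) and two
Gaussian fits, and tabulate Kullback–Leibler distance and FWHM:

```sh
tofpet reproduce-idealised --n-events 1000000 --seed 1 --out ideal-demo
```

```
 L_mm             kernel       kl   fwhm_ps
 10.0                ctr 0.000029 30.340603
 10.0   gaussian_bounded 0.007668 31.466229
 10.0 gaussian_unbounded 0.007688 31.459059
 20.0                ctr 0.000069 47.113664
 20.0   gaussian_bounded 0.007820 59.661517
 20.0 gaussian_unbounded 0.007825 59.657095
 40.0                ctr 0.000152 52.853664
 40.0   gaussian_bounded 0.020943 99.067389
 40.0 gaussian_unbounded 0.020944 99.064063
```

The CTR kernel matches the simulated timing response to within the
sampling-noise floor (K-L ~ 10⁻⁴ nats at 10⁶ events), while the best
Gaussian fits are two orders of magnitude worse and increasingly so for
thicker crystals, where the kernel's exponential peak and shoulders deviate
most from a bell curve.  The FWHM column shows the physical story: the
40-mm crystal's timing response has a 53-ps-wide core, but a Gaussian fit
inflates it to 99 ps.

A full 2-D imaging experiment chains the other subcommands:

```sh
tofpet simulate-scan --phantom nema --crystal-length 40 --n-detectors 180 \
    --n-events 400000 --seed 11 --out nema.tsv
tofpet reconstruct nema.tsv --kernel-kind ctr --n-iter 60 --snapshots 60 \
    --grid-size 128 --out recon/
tofpet evaluate recon/recon_ctr_iter060.f32 --phantom nema --out crc.tsv
```

which prints one contrast-recovery row per hot sphere (10/13/17/22 mm).

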