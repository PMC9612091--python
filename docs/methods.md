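# Methods

## Forward model and inversion

The reflectance kernel is the diffusion approximation for a homogeneous
semi-infinite medium under spatially modulated irradiance. With
μtr = μa + μs′, a′ = μs′/μtr, μeff = √(3 μa μtr) and
μ′eff(fx) = √(μeff² + (2π fx)²),

    Rd = 3 A a′ / ((μ′eff/μtr + 1)(μ′eff/μtr + 3A)),
    A  = (1 − Reff) / (2 (1 + Reff)),
    Reff = 0.0636 n + 0.668 + 0.710/n − 1.440/n²,

with relative refractive index n = 1.4 by default (tissue/water against
air). Experimental SFDI pipelines usually invert a Monte Carlo-generated
table instead; here the closed form is the default table generator because
it is deterministic and desk-scale, and the inversion machinery is
independent of the table's origin — `load_lut` accepts an externally
computed table with the same schema (grid + Rd at the two frequencies).

The default table spans μa ∈ [0.001, 0.2] mm⁻¹ (128 log-spaced nodes; Rd
varies fastest at low absorption) × μs′ ∈ [0.3, 6] mm⁻¹ (128 linear nodes),
a deliberate superset of the tissue/phantom ranges (μa 0.0067–0.082,
μs′ 0.67–4.2 mm⁻¹) so noisy pixels rarely leave the grid. Inversion takes
the nearest table node in reflectance space (KD-tree, per-axis scaled) as
the initial guess and polishes with a damped, bound-projected 2×2 Newton
iteration on the continuous forward model (relative FD step 1e-6, stop at
residual 1e-12, steps clipped to factor-2 moves to preserve positivity).
Round trips are exact to ~1e-13 relative, far inside the 0.5% contract;
doubling the grid density moves results by <0.1%, confirming the table only
serves as a seed. Reflectance pairs outside the attainable set (or outside
(0,1)) are clamped to the boundary and **flagged, never NaN'd**, so
downstream unmixing stays total; flagged counts are logged per map.

One model caveat: at fx = 0.2 mm⁻¹ the closed form is mildly non-monotone
in μa for μs′ below ~0.55 mm⁻¹ (inside the margin of the default grid,
outside the validated ranges). Within the validated ranges Rd is strictly
decreasing in μa and fx and increasing in μs′, and the tests assert exactly
that.

The effective penetration depth is the standard δ′eff = 1/μ′eff(fx). On the
packaged 10% intralipid properties this gives ≈0.77 mm at fx = 0.2 and
≈0.39 mm at fx = 0.4 mm⁻¹ averaged over 900–1000 nm. Larger figures
(≈2 / 1.6 mm) are sometimes quoted for the same frequencies from other
depth definitions (e.g. photon-path percentile sampling depth) or other
property assumptions; this package implements only the standard
diffusion-theory definition and documents the discrepancy rather than
tuning properties to match.

## Demodulation and calibration

Three-phase demodulation uses the prefactor √2/3, which returns exactly the
sinusoidal AC amplitude for ideal frames (the trigonometric identity makes
the phase-difference sum equal 3/√2 times the amplitude); any constant here
cancels in calibration, so pipelines that use other constants produce
identical reflectance. The white/black pair gives the planar component
(white − black, floored at 0); the black frame doubles as the dark
reference. Dark subtraction of the sinusoidal frames is unnecessary because
phase differencing removes common offsets. Calibration divides demodulated
sample by demodulated reference and multiplies by the reference phantom's
forward-model reflectance at the same (wavelength, fx); the packaged
reference is a 10% intralipid fixture. Non-positive reference pixels yield
NaN plus a flag rather than infinities.

Drift correction targets slow multiplicative source drift: a small
reference tile kept in the field of view defines per-time correction
factors mean(tile, baseline)/mean(tile, t), applied per wavelength and
frequency. A global multiplicative drift is removed exactly; drift confined
outside the tile is by construction untouched — the correction is a scalar
per (wavelength, fx, time), matching the single-tile protocol it emulates.

## Chromophore basis and unmixing

Water and lipid are reported in percent volume fraction, hemoglobins in µM;
the basis matrix is scaled accordingly so `matrix @ c` is μa in mm⁻¹.
The default fit is non-negative least squares (physical concentrations;
avoids negative fractions at low SNR), with an unconstrained mode for
diagnostics. No sum-to-100% constraint is imposed — the study's sampling
ranges deliberately allow joint sums above 100%. NaN wavelengths are masked
when at least as many wavelengths as chromophores remain. The batch fitter
solves the unconstrained normal equations for all pixels at once and falls
back to NNLS only for rows with a negative component (the two solutions
coincide whenever the unconstrained optimum is feasible), which keeps
per-image unmixing vectorized.

The packaged extinction spectra are **synthetic fixtures**: smooth
monotone-cubic constructions through anchor points at the standard NIR
features (970-nm water peak ≈0.0485 mm⁻¹ at unit fraction, 930-nm lipid
peak ≈0.011 mm⁻¹, the HbO2 NIR plateau and the 760-nm HHb peak), generated
by `scripts/make_fixture_spectra.py` and labelled as such in each CSV
header. Everything validated here — basis rank, unbiased refits, CRB
orderings, end-to-end closure — depends on realistic shapes and magnitudes,
not on any particular literature tabulation; quantitative work on real data
should substitute measured extinction tables via the same CSV schema.

## Cramér–Rao frequency design

For a two-frequency measurement with independent Gaussian reflectance noise
the bound is σ = √diag(F⁻¹), F = Jᵀ Σ⁻¹ J, with J the central-difference
Jacobian of (Rd(f1), Rd(f2)) in (μa, μs′) (relative step 1e-4;
convergence-tested) and Σ built from a two-parameter noise model
sd(f) = σ0 + σ1·Rd(f), defaults σ0 = 0.002, σ1 = 0.01. Real instruments
have their own noise parameters, which are rarely published; the defaults
are a stand-in, so **only orderings and scalings of the bounds are
meaningful**, and that is all the tests assert: [0, 0.05] mm⁻¹ is the worst
of the four candidate pairs on intralipid-like properties across
900–1000 nm (its two sensitivity vectors are nearly parallel), the bounds
scale linearly with a global noise factor, and the ranking is
scale-invariant.

Pair selection is made explicit as: lowest mean σ_μa among pairs whose mean
effective penetration depth at the higher frequency (on the intralipid
reference properties) is at least 0.7 mm — deep enough to cover dermis plus
subcutis in small-animal work. This keeps [0, 0.2] (≈0.77 mm) and excludes
[0, 0.4] (≈0.39 mm); both thresholds are config-exposed because the
underlying criterion is a judgment call, not a formula.

## Wavelength-increment study

100,000 (water, lipid) pairs are drawn independently and uniformly from
15–90% and 20–80%. For each increment (1, 2, 5, 10 nm) the Beer's-law
spectrum is synthesized on that grid, zero-mean Gaussian noise is added per
wavelength, and both concentrations are refit by NNLS. Percent error is
100·(estimate − truth)/truth. Because the noise is zero-mean and truth ≥15%
keeps the non-negativity constraint inactive, the refit is unbiased: mean
percent errors are pure Monte Carlo residue (≲0.006% at n = 100,000), while
the sd per increment measures the information content of the grid and
shrinks roughly like 1/√(number of wavelengths) — observed sd ratios vs
1 nm are ≈1.4 (2 nm), ≈2.2 (5 nm), ≈3.1 (10 nm) for both chromophores.

Noise magnitude: the per-wavelength sd is tied to the measurement physics
by taking σ_μa from the CRB at the working [0, 0.2] pair, evaluated at each
sample's true absorption and a power-law scattering spectrum
μs′(λ) = 2.0·(λ/1000 nm)^(−1.3) mm⁻¹ (inside the phantom range). The CRB
noise model describes **single-pixel** reflectance noise, whereas the
study's spectra emulate ROI-averaged measurements (a ~1×0.5 cm region is
hundreds of pixels), so the default `noise_scale = 0.1` applies the ~10×
sd reduction of averaging ≈100 pixels. Both the scale and a constant-sd
mode (one sd per increment, evaluated at mid-range concentrations) are
config-exposed; per-wavelength mode is the default.

Increment selection: coarsest increment whose percent-error sd stays within
a factor (default 2.5) of the 1-nm sd for both chromophores. With the
observed ≈√n scaling this admits 5 nm (ratio ≈2.2) and rejects 10 nm
(≈3.1) — the intended reading of "acceptable error inflation for 5× fewer
acquisitions". The factor is config-exposed.

## Synthetic scenes and renderer

Scenes carry per-pixel concentration maps, power-law scattering parameters
and a pixel pitch (default 0.1 mm/px); templates cover a homogeneous
phantom, a two-region patch and an injection-blob time series (Gaussian
water blob growing over a baseline). The renderer composes ideal sinusoidal
frames along the image x-axis (spatial frequency in sample-plane mm⁻¹ via
the pixel pitch), with illumination DC/AC levels, gain, dark level and
additive Gaussian camera noise (default sd 2 counts against a ~1000-count
DC level, i.e. a well-exposed frame); frames are floored at zero. Projector
blur/MTF, specular reflections, surface curvature and realistic skin
layering are deliberately not modelled: the rendered AC amplitude is exactly
proportional to Rd(fx), which makes the processing chain algebraically
exact in the noiseless limit (closure to <1e-10 relative is a test). A
homogeneous-phantom default ties scattering to the lipid emulsion content
(μs′ amplitude 0.18·lipid% mm⁻¹ at 1000 nm, so 10% lipid ≈ 1.8 mm⁻¹ at
800 nm), mirroring how intralipid dilutions behave.

Passing the end-to-end tests therefore shows the *processing* is correct
and unbiased under the renderer's idealizations — it does not certify
accuracy on real instruments, where MTF, height/curvature and phase errors
enter; those effects are out of scope.

## Problem sizes and numerical defaults

The test suite and the acceptance script run the study at its full
n = 100,000 (vectorized batch fitting makes this a few seconds); image
tests use 16–48 px square scenes and 21 wavelengths, large enough to
exercise every code path while keeping the whole suite under a minute.
Key tolerances: inversion round-trip contract 0.5% relative (achieved
~1e-13), chain closure 1e-10 relative, CRB FD convergence 0.1%, NNLS
fallback budget 1% of study samples (exceeding it raises rather than
silently biasing the statistics).

## Known limitations

- Homogeneous, semi-infinite, single-layer diffusion model per pixel;
  partial-volume effects across depth are acknowledged, not modelled.
- The diffusion approximation degrades at high absorption/low scattering
  (μs′/μa small) and at high spatial frequencies; the Monte Carlo import
  path exists for exactly that reason.
- Synthetic extinction fixtures: shapes are realistic, values are not a
  literature tabulation (see above).
- CRB absolute values depend on unpublished instrument noise; only
  orderings are asserted.
- The renderer's idealizations listed above.
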