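# sfdikit

Spatial frequency domain imaging (SFDI) toolkit for quantitative, label-free
mapping of **tissue water and lipid content in the 900–1000 nm window** — the
spectral region where a regular silicon camera still sees both the 970-nm
water and the 930-nm lipid absorption features.

SFDI projects sinusoidal light patterns at known spatial frequencies onto a
turbid sample and images the diffusely reflected light. From a pair of
spatial frequencies it separates absorption from scattering per pixel; from
a set of wavelengths it separates chromophores. `sfdikit` implements the
full processing chain plus the measurement-design analyses used to choose
the acquisition settings, and a synthetic acquisition renderer that closes
the loop for testing — no instrument required.

## What it computes

1. **Demodulation** — three frames at pattern phases 0°/120°/240° reduce to
   the per-pixel AC amplitude
   `I = (√2/3)·√((I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²)`;
   a white/black pair gives the planar (fx = 0) component.
2. **Calibration** — `R_d(fx) = I(fx)/I_ref(fx) · R_d,ref(fx)` against a
   reference phantom of known optical properties (packaged 10% intralipid
   fixture), cancelling source and camera gain.
3. **Optical-property inversion** — the diffusion-approximation forward
   model `R_d(μa, μs′, fx)` for a semi-infinite homogeneous medium is
   tabulated over a (μa, μs′) grid and inverted per pixel from the
   reflectance pair (lookup + Newton polish; round trip exact to ~1e-10,
   contract 0.5%). An externally computed (e.g. Monte Carlo) table with the
   same schema can be swapped in.
4. **Beer's-law unmixing** — `μa(λ) = Σᵢ cᵢ·εᵢ(λ)` solved per pixel by
   non-negative least squares for water/lipid (percent volume fraction) and
   optionally oxy-/deoxyhemoglobin (µM, requires wavelengths below 900 nm).
5. **Measurement design** — Cramér–Rao bounds
   `σ = √diag((Jᵀ Σ⁻¹ J)⁻¹)` rank candidate spatial-frequency pairs
   ([0,0.05], [0,0.1], [0,0.2], [0,0.4] mm⁻¹), and a 100,000-sample
   simulation quantifies the accuracy/speed tradeoff of 1/2/5/10-nm
   wavelength increments.
6. **Drift correction** — an in-field reference tile rescales a time series
   so multiplicative source drift cancels exactly.

## Worked example

```bash
python examples/06_end_to_end_phantom.py
```

renders a homogeneous 85% water / 15% lipid phantom with default camera
noise, runs the full chain and prints

```
 roi chromophore                    unit      mean       sd  n_pixels  n_nan
   0       water percent volume fraction 85.122798 1.564976       317      0
   0       lipid percent volume fraction 14.838259 4.514904       317      0
out-of-range pixels: 0
```

— the ROI mean recovers the known recipe within ~0.2 percentage points; the
per-pixel sd reflects the injected camera noise, and no pixel fell outside
the lookup table. The other examples (`examples/01…05`) walk each stage
separately: demodulation/calibration, property inversion, unmixing, the CRB
frequency ranking, and the wavelength-increment study.

A thin CLI wraps the same library calls:

```bash
sfdikit simulate --water 90 --lipid 10 --out run/
sfdikit process --sample run/sample.tif --reference run/reference.tif --out run/out
sfdikit crb-scan --out run/design
sfdikit wavelength-study --n-samples 20000 --out run/design
```

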