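# lampvision

Street lighting has been shifting from narrow-spectrum low-pressure sodium
(LPS) lamps toward broad-spectrum technologies — high-pressure sodium (HPS),
light-emitting diodes (LED) and metal halide (MH). Because animal taxa differ
widely in the region of the spectrum their photoreceptors can detect
(insects, arachnids and many reptiles see into the UV; most mammals are
dichromats with no UV sensitivity), a change of lamp technology changes
*which animals* can see well under artificial light. `lampvision` is a small
analysis library for vision ecologists that quantifies this.

## What it computes

1. **Pigment modelling.** A visual pigment's absorbance spectrum is
   reconstructed from its peak wavelength λ_max with the standard A1
   template: an α-band
   `S_α(x) = 1 / (e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D)`, `x = λ_max/λ`,
   plus a Gaussian β-band whose centre and width are linear in λ_max.
   Curves are evaluated on 200–750 nm and normalized to peak 1.
2. **Ocular filtering.** Bird and diurnal-reptile single cones sit behind
   oil droplets — long-pass filters parameterized by the cut-off wavelength
   λ_cut or the half-transmittance wavelength λ_mid (related by
   λ_mid = λ_cut + 0.5/B_mid, with edge slope B_mid). The transmittance
   edge is a Gompertz-type double exponential with T(λ_mid) = 0.5. UV cones
   and nocturnal reptiles carry clear (identity) droplets.
3. **Visual range.** For each species, the λ_0.5 range: the interval between
   the outermost wavelengths at which any of its (filtered) pigments absorbs
   more than half its maximum — min λ_0.5 to max λ_0.5.
4. **Lamp emission range.** From a two-column spectrometer file (or a
   synthetic archetype), the region where baseline-corrected irradiance
   exceeds 1% of its peak (λ_light range).
5. **The index.** `% λ_0.5 range` = 100 × |visual ∩ emission| / |visual| —
   the percentage of a species' visually detectable range that a lamp
   stimulates.
6. **Group comparison.** Posterior means and 95% credibility intervals of
   the index per class × lamp (zero-intercept cell-means Gibbs regression,
   iterations 1001:11000), and pairwise lamp/class differences from
   fitted-intercept refits; a difference whose interval excludes 0 is
   treated as credible.

Because real λ_max compilations and measured lamp spectra are not bundled,
the package ships a seeded synthetic generator producing a 213-species
fleet (7 arachnids, 112 insects, 16 birds, 32 reptiles, 46 mammals) and four
archetype lamp spectra with the qualitative structure of the real
technologies.

## Worked example

```bash
python examples/03_lamp_overlap.py
```

```
bee-like insect: visual range 295-579 nm
  LPS emits   567-  617 nm -> stimulates   4.1% of the visual range
  HPS emits   440-  680 nm -> stimulates  48.9% of the visual range
  LED emits   442-  665 nm -> stimulates  48.3% of the visual range
  MH  emits   372-  695 nm -> stimulates  72.8% of the visual range

rodent-like mammal: visual range 379-595 nm
  LPS emits   567-  617 nm -> stimulates  13.0% of the visual range
  HPS emits   440-  680 nm -> stimulates  71.9% of the visual range
  LED emits   442-  665 nm -> stimulates 71.0% of the visual range
  MH  emits   372-  695 nm -> stimulates 100.0% of the visual range
```

The UV-sensitive insect's visual range reaches to ~295 nm, far below any
lamp's emission, so even broad lamps stimulate only half to three quarters
of it; the mammal's UV-blind range is almost fully covered by MH light.
`examples/04_full_analysis.py` runs the full 213-species fleet and prints
the posterior class × lamp means, a pairwise credibility-interval table and
the per-lamp counts of credible class differences.

There is also a thin CLI over the same functions:

```bash
lampvision synth --seed 1 --out inputs/        # write synthetic inputs
lampvision all --synthetic --seed 1 --out results/
lampvision all --species inputs/species.csv \
    --lamp LPS=inputs/lamp_LPS.txt --lamp MH=inputs/lamp_MH.txt --out results/
```

Every output CSV carries a comment header echoing the full configuration
and its hash.

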